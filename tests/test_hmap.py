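import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recmap import hmap
from recmap.hmap import (
    PhasedGenotypeMatrix, bonferroni_threshold, extract_interval,
    fisher_exact_2x2, predict_status, scan, top_windows,
)
from recmap.simulate import SimulationConfig, simulate_population

from conftest import make_matrix


def fisher_oracle(a, b, c, d) -> float:
    """Exhaustive hypergeometric enumeration of the two-sided p-value."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = [math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
             for k in range(lo, hi + 1)]
    p_obs = probs[a - lo]
    return min(1.0, sum(p for p in probs if p <= p_obs * (1 + 1e-7)))


class TestFisher:
    @pytest.mark.parametrize("table,expected", [
        ((2, 1, 1, 2), 1.0),
        ((0, 7, 0, 13), 1.0),                     # degenerate column
        ((5, 0, 0, 5), 2 / math.comb(10, 5)),     # 2/252
        ((0, 0, 0, 0), 1.0),                      # all-zero, by convention
    ])
    def test_hand_enumerated_tables(self, table, expected):
        assert fisher_exact_2x2(*table) == pytest.approx(expected, rel=1e-9)

    def test_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 16, size=4)
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_oracle(a, b, c, d), rel=1e-6)

    def test_case_control_extreme_table(self):
        # every case homozygous, no control: the tail is a single point mass
        assert fisher_exact_2x2(21, 0, 0, 1548) == pytest.approx(
            fisher_oracle(21, 0, 0, 1548), rel=1e-9)

    @given(st.tuples(*[st.integers(0, 12)] * 4))
    @settings(max_examples=60, deadline=None)
    def test_invariant_under_double_transposition(self, table):
        a, b, c, d = table
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            fisher_exact_2x2(d, c, b, a), rel=1e-9)

    def test_monotone_toward_the_extreme(self):
        # fixed margins 10/10, column total 10: p falls as a moves to 10
        ps = [fisher_exact_2x2(a, 10 - a, 10 - a, a) for a in range(5, 11)]
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 0, 0, 1)


class TestBonferroni:
    @pytest.mark.parametrize("alpha,n,expected", [
        (0.05, 78861, 6.20),
        (0.05, 1, 1.301),
        (1.0, 1, 0.0),
    ])
    def test_threshold_values(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected, abs=5e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


def _uniform_hom_matrix(n_cases, n_controls, m=25):
    haps = np.zeros((n_cases + n_controls, 2, m), dtype=np.uint8)
    # same homozygous haplotype for everyone, with one varying marker for MAF
    haps[: (n_cases + n_controls) // 2, :, 0] = 1
    return make_matrix(haps)


class TestScan:
    def test_everyone_homozygous_gives_p_one(self):
        gmat = _uniform_hom_matrix(4, 6)
        cases = gmat.individuals[:4]
        controls = gmat.individuals[4:]
        tests = scan(gmat, cases, controls, window_size=5, maf_floor=-1.0)
        assert tests
        for t in tests:
            assert t.a + t.b == 4 and t.c + t.d == 6
            if t.b == 0 and t.c == 6:            # the shared haplotype
                assert t.p_value == pytest.approx(1.0)

    def test_overlapping_cases_and_controls_rejected(self):
        gmat = _uniform_hom_matrix(2, 2)
        with pytest.raises(ValueError, match="overlap"):
            scan(gmat, gmat.individuals[:2], gmat.individuals[1:])

    def test_window_wider_than_chromosome_skipped(self):
        gmat = _uniform_hom_matrix(2, 2, m=6)
        tests = scan(gmat, gmat.individuals[:2], gmat.individuals[2:],
                     window_size=50)
        assert tests == []

    def test_tests_match_enumeration_rule(self):
        """One test per (window, haplotype homozygous in >= 1 case)."""
        rng = np.random.default_rng(0)
        haps = rng.integers(0, 2, size=(30, 2, 40)).astype(np.uint8)
        gmat = make_matrix(haps)
        cases, controls = gmat.individuals[:6], gmat.individuals[6:]
        w = 4
        tests = scan(gmat, cases, controls, window_size=w, maf_floor=0.0)
        expected = 0
        for s in range(40 - w + 1):
            case_haps = haps[:6, :, s:s + w]
            hom = (case_haps[:, 0] == case_haps[:, 1]).all(axis=1)
            expected += len({case_haps[i, 0].tobytes()
                             for i in np.flatnonzero(hom)})
        assert len(tests) == expected


class TestMappingInterval:
    def _paper_geometry(self):
        """Synthetic genotypes reproducing the published interval geometry:
        a 35-marker homozygous run flanked by the most proximal markers."""
        run = list(np.linspace(3_583_342, 5_092_017, 35).astype(int))
        run[0], run[-1] = 3_583_342, 5_092_017
        positions = [3_500_000, 3_555_723] + run + [5_143_700, 5_200_000]
        m = len(positions)
        n_cases, n_controls = 4, 8
        haps = np.zeros((n_cases + n_controls, 2, m), dtype=np.uint8)
        run_cols = slice(2, 2 + 35)
        # cases: homozygous 0...0 inside the run only (het at the flanks)
        haps[:n_cases, 1, :2] = 1
        haps[:n_cases, 1, 2 + 35:] = 1
        # controls: heterozygous everywhere, never homozygous
        haps[n_cases:, 1, :] = 1
        gmat = make_matrix(haps, positions=positions, chrom=28)
        return gmat, gmat.individuals[:n_cases], gmat.individuals[n_cases:]

    def test_interval_bounded_by_proximal_outside_markers(self):
        gmat, cases, controls = self._paper_geometry()
        tests = scan(gmat, cases, controls, window_size=20, maf_floor=0.0)
        res = extract_interval(tests, gmat, cases, controls, maf_floor=0.0)
        assert res.merged_haplotype_span == (28, 3_583_342, 5_092_017, 35)
        assert res.interval == (28, 3_555_723, 5_143_700)
        assert res.interval_width_bp == 5_143_700 - 3_555_723
        assert res.risk_haplotype == "0" * 35
        # interval strictly contains the merged span (no chromosome edge here)
        assert res.interval[1] < res.merged_haplotype_span[1]
        assert res.interval[2] > res.merged_haplotype_span[2]

    def test_run_at_chromosome_edge_is_truncated(self):
        rng = np.random.default_rng(1)
        m = 30
        haps = rng.integers(0, 2, (10, 2, m)).astype(np.uint8)
        # cases homozygous over the first 22 markers only
        haps[:2, 0, :22] = 0
        haps[:2, 1, :22] = 0
        haps[:2, 1, 22:] = 1 - haps[:2, 0, 22:]
        gmat = make_matrix(haps)
        cases, controls = gmat.individuals[:2], gmat.individuals[2:]
        tests = scan(gmat, cases, controls, window_size=20, maf_floor=0.0)
        res = extract_interval(tests, gmat, cases, controls, maf_floor=0.0)
        assert res.interval is not None
        assert res.interval[1] == res.merged_haplotype_span[1]  # truncated left
        assert "edge" in res.diagnostics

    def test_no_qualifying_window_reports_diagnostic(self):
        # cases and controls all homozygous for the same haplotype
        gmat = make_matrix(np.zeros((6, 2, 25), dtype=np.uint8))
        cases, controls = gmat.individuals[:3], gmat.individuals[3:]
        tests = scan(gmat, cases, controls, window_size=5, maf_floor=-1.0)
        res = extract_interval(tests, gmat, cases, controls, maf_floor=-1.0)
        assert res.interval is None and res.diagnostics

    def test_result_independent_of_test_order(self):
        gmat, cases, controls = self._paper_geometry()
        tests = scan(gmat, cases, controls, window_size=20, maf_floor=0.0)
        rng = np.random.default_rng(3)
        shuffled = list(tests)
        rng.shuffle(shuffled)
        a = extract_interval(tests, gmat, cases, controls, maf_floor=0.0)
        b = extract_interval(shuffled, gmat, cases, controls, maf_floor=0.0)
        assert a.interval == b.interval
        assert a.merged_haplotype_span == b.merged_haplotype_span


class TestSimulatedMapping:
    def test_top_plateau_overlaps_simulated_locus(self, mapped_pop):
        pop = mapped_pop
        cfg = pop.config
        cases = pop.ascertained_ids
        controls = [i for i in pop.survivor_ids()
                    if pop.risk_genotypes[i] == 0][:1548]
        tests = scan(pop.genotypes, cases, controls)
        plateau = top_windows(tests)
        assert all(t.chrom == cfg.risk_locus_chrom for t in plateau)
        span = (min(t.pos_start for t in plateau),
                max(t.pos_end for t in plateau))
        assert span[0] <= cfg.risk_locus_pos <= span[1]
        res = extract_interval(tests, pop.genotypes, cases, controls)
        assert res.interval[0] == cfg.risk_locus_chrom
        assert res.interval[1] <= cfg.risk_locus_pos <= res.interval[2]

    def test_haplotype_test_recovers_carrier_status(self, mapped_pop):
        """Carrier-status prediction from the merged haplotype matches the
        simulated risk dosage for at least 99% of individuals."""
        pop = mapped_pop
        cases = pop.ascertained_ids
        controls = [i for i in pop.survivor_ids()
                    if pop.risk_genotypes[i] == 0][:1548]
        tests = scan(pop.genotypes, cases, controls)
        res = extract_interval(tests, pop.genotypes, cases, controls)
        H = pop.genotypes.haplotypes[:, :, res.marker_indices]
        hits = sum(
            predict_status(H[i], res.risk_haplotype) == pop.risk_genotypes[iid]
            for i, iid in enumerate(pop.genotypes.individuals))
        assert hits / pop.genotypes.n_individuals >= 0.99


class TestPredictStatus:
    def test_dosage_counting(self):
        risk = "0110"
        both = np.array([[0, 1, 1, 0], [0, 1, 1, 0]])
        neither = np.array([[1, 1, 1, 0], [0, 0, 1, 0]])
        one = np.array([[0, 1, 1, 0], [1, 1, 1, 1]])
        assert predict_status(both, risk) == 2
        assert predict_status(neither, risk) == 0
        assert predict_status(one, risk) == 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            predict_status(np.zeros((2, 3)), "0110")


class TestNullScanCalibration:
    def test_bonferroni_controls_null_exceedances(self):
        """Without an embedded locus, windows past the threshold are rare."""
        exceed, total = 0, 0
        for seed in range(20):
            cfg = SimulationConfig(
                n_founders=150, n_generations=2, n_markers=150,
                n_chromosomes=1, chromosome_length_bp=6_000_000,
                risk_allele_freq=0.0, risk_locus_pos=3_000_000, seed=seed)
            pop = simulate_population(cfg)
            rng = np.random.default_rng(seed)
            ids = pop.genotypes.individuals
            cases = list(rng.choice(ids, size=12, replace=False))
            controls = [i for i in ids if i not in set(cases)][:120]
            tests = scan(pop.genotypes, cases, controls)
            if not tests:
                continue
            thr = bonferroni_threshold(0.05, len(tests))
            exceed += sum(t.neg_log10_p > thr for t in tests)
            total += len(tests)
        assert total > 0
        assert exceed / total <= 0.05
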