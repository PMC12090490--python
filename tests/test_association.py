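import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from recmap.association import (
    bh_qvalues, effect_in_gsd, grm, grm_eig, mlma,
)

from conftest import make_matrix

# Raw p-values as printed in the mortality-contrast and performance-trait
# analyses (three contrasts x five periods; five traits).
MORTALITY_P = {
    ("56-365", "1x1"): 0.44, ("56-365", "1x0"): 0.72, ("56-365", "0x1"): 0.60,
    ("15-55", "1x1"): 0.48, ("15-55", "1x0"): 0.63, ("15-55", "0x1"): 0.11,
    ("3-14", "1x1"): 0.02, ("3-14", "1x0"): 0.54, ("3-14", "0x1"): 0.15,
    ("0-2", "1x1"): 1.59e-11, ("0-2", "1x0"): 0.03, ("0-2", "0x1"): 0.89,
    ("0-14", "1x1"): 1.32e-11, ("0-14", "1x0"): 0.15, ("0-14", "0x1"): 0.49,
}
TRAIT_P = [0.54, 0.91, 0.04, 0.61, 0.53]        # five performance traits


def bh_oracle(pvals):
    """Independent step-up oracle: q_i = min over thresholds t >= p_i of
    t * n / #{p <= t}."""
    p = np.asarray(pvals, float)
    n = len(p)
    out = np.empty(n)
    for i, pi in enumerate(p):
        cands = [t * n / (p <= t).sum() for t in p if t >= pi]
        out[i] = min(1.0, min(cands))
    return out


class TestGrm:
    def test_single_marker_closed_forms(self):
        # p = 0.5; dosages 2 and 0 -> W = [1, -1], denom = 0.5
        G = grm(np.array([[2.0], [0.0]]))
        assert G[0, 0] == pytest.approx(2.0)
        assert G[0, 1] == pytest.approx(-2.0)
        assert G[1, 1] == pytest.approx(2.0)

    def test_row_sums_vanish_at_sample_frequencies(self):
        rng = np.random.default_rng(2)
        X = rng.binomial(2, rng.uniform(0.1, 0.9, 300), (80, 300)).astype(float)
        G = grm(X)
        assert np.allclose(G.sum(axis=1), 0.0, atol=1e-9)
        assert np.allclose(G, G.T)

    def test_monomorphic_markers_dropped(self):
        X = np.array([[2.0, 2.0], [0.0, 2.0]])
        G = grm(X)                      # second marker is monomorphic
        assert G[0, 0] == pytest.approx(2.0)

    def test_half_sib_families_average_quarter(self):
        """Mean genomic relationship of half sibs approaches the pedigree
        expectation of 0.25."""
        rng = np.random.default_rng(5)
        m, n_sires, n_off = 3000, 25, 12
        p = rng.uniform(0.1, 0.9, m)
        sire_h = rng.random((n_sires, 2, m)) < p
        rows, fam = [], []
        for s in range(n_sires):
            for _ in range(n_off):
                pat = np.where(rng.random(m) < 0.5, sire_h[s, 0], sire_h[s, 1])
                mat = rng.random(m) < p
                rows.append(pat.astype(int) + mat.astype(int))
                fam.append(s)
        G = grm(np.array(rows, float))
        fam = np.array(fam)
        same = (fam[:, None] == fam[None, :]) & ~np.eye(len(fam), dtype=bool)
        vals = G[same]
        se = vals.std() / np.sqrt(n_sires)      # families are the unit
        assert abs(vals.mean() - 0.25) < 3 * se + 0.01

    def test_exclude_chromosome(self):
        rng = np.random.default_rng(3)
        haps = (rng.random((30, 2, 40)) < 0.5).astype(np.uint8)
        gmat = make_matrix(haps)
        full = grm(gmat)
        assert full.shape == (30, 30)
        with pytest.raises(ValueError):
            grm(gmat.exclude_chrom(1))          # all markers removed

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError):
            grm(np.array([[1.0, 0.0]]))


@pytest.fixture(scope="module")
def cohort():
    rng = np.random.default_rng(7)
    n, m = 1200, 600
    p = rng.uniform(0.05, 0.95, m)
    X = rng.binomial(2, p, (n, m)).astype(float)
    G = grm(X)
    return G, grm_eig(G), rng


class TestMlma:
    def test_collapses_to_ols_without_polygenic_variance(self, cohort):
        G, eig, rng = cohort
        n = G.shape[0]
        x = (rng.random(n) < 0.05).astype(float)
        y = 1.0 + 0.8 * x + rng.standard_normal(n)
        res = mlma(y, x, eig=eig, h2=0.0)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.b == pytest.approx(ols.params[1], rel=1e-9)
        assert res.se == pytest.approx(ols.bse[1], rel=0.01)  # df convention
        assert res.p_value == pytest.approx(ols.pvalues[1], rel=0.05)

    def test_recovers_simulated_effect(self, cohort):
        G, (d, U), rng = cohort
        n = G.shape[0]
        x = (rng.random(n) < 0.06).astype(float)
        su2, se2 = 3.0, 7.0
        bs = []
        for _ in range(25):
            u = U @ (np.sqrt(np.clip(d, 0, None) * su2) * rng.standard_normal(n))
            y = 5.0 - 1.0 * x + u + rng.normal(0, np.sqrt(se2), n)
            bs.append(mlma(y, x, eig=(d, U)).b)
        se = np.std(bs, ddof=1) / np.sqrt(len(bs))
        assert abs(np.mean(bs) + 1.0) < 3 * se

    def test_estimates_heritability_under_null(self, cohort):
        G, (d, U), rng = cohort
        n = G.shape[0]
        u = U @ (np.sqrt(np.clip(d, 0, None) * 4.0) * rng.standard_normal(n))
        y = u + rng.normal(0, np.sqrt(6.0), n)
        res = mlma(y, np.zeros(n) + (rng.random(n) < 0.5), eig=(d, U))
        assert 0.1 < res.h2 < 0.8
        assert res.sigma_u2 > 0 and res.sigma_e2 > 0

    def test_zero_variance_phenotype_rejected(self, cohort):
        G, eig, _ = cohort
        n = G.shape[0]
        with pytest.raises(ValueError):
            mlma(np.ones(n), np.zeros(n), eig=eig)

    def test_non_psd_matrix_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="semidefinite"):
            grm_eig(bad)


class TestEffectScaling:
    def test_published_scaling(self):
        assert round(100 * effect_in_gsd(-1.00, 4.77)) == 21

    @pytest.mark.parametrize("b,gsd,expected", [(0.0, 3.0, 0.0), (2.5, 2.5, 1.0)])
    def test_edge_values(self, b, gsd, expected):
        assert effect_in_gsd(b, gsd) == expected

    def test_nonpositive_gsd_rejected(self):
        with pytest.raises(ValueError):
            effect_in_gsd(1.0, 0.0)


class TestBhQvalues:
    def test_five_trait_family_reproduces_printed_q(self):
        q = bh_qvalues(TRAIT_P)
        assert q[TRAIT_P.index(0.04)] == pytest.approx(0.20)
        printed = [0.76, 0.91, 0.20, 0.76, 0.76]
        assert np.round(q, 2).tolist() == printed

    def test_five_contrast_family_reproduces_printed_q(self):
        p = [MORTALITY_P[(per, "1x1")]
             for per in ("56-365", "15-55", "3-14", "0-2", "0-14")]
        q = bh_qvalues(p)
        assert q[3] == pytest.approx(3.98e-11, rel=5e-3)
        assert q[4] == pytest.approx(3.98e-11, rel=5e-3)
        assert q[2] == pytest.approx(0.0333, abs=5e-4)   # printed 0.03
        assert q[0] == pytest.approx(0.48, abs=5e-3)

    def test_fifteen_test_family_to_two_significant_figures(self):
        keys = list(MORTALITY_P)
        q = bh_qvalues([MORTALITY_P[k] for k in keys])
        printed = {
            ("56-365", "1x1"): 0.73, ("56-365", "1x0"): 0.77,
            ("56-365", "0x1"): 0.73,
            ("15-55", "1x1"): 0.73, ("15-55", "1x0"): 0.73,
            ("15-55", "0x1"): 0.32,
            ("3-14", "1x1"): 0.10, ("3-14", "1x0"): 0.73,
            ("3-14", "0x1"): 0.32,
            ("0-2", "1x1"): 1.20e-10, ("0-2", "1x0"): 0.11,
            ("0-2", "0x1"): 0.89,
            ("0-14", "1x1"): 1.20e-10, ("0-14", "1x0"): 0.32,
            ("0-14", "0x1"): 0.73,
        }
        for k, qi in zip(keys, q):
            assert float(f"{qi:.2g}") == pytest.approx(printed[k], rel=1e-9), k

    def test_single_p_is_its_own_q(self):
        assert bh_qvalues([0.37])[0] == pytest.approx(0.37)

    def test_empty_input(self):
        assert bh_qvalues([]).size == 0

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    @settings(max_examples=80, deadline=None)
    def test_matches_threshold_oracle_and_invariants(self, pvals):
        q = bh_qvalues(pvals)
        oracle = bh_oracle(pvals)
        assert np.allclose(q, oracle, atol=1e-12)
        p = np.array(pvals)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= np.minimum(1.0, p * len(p)) + 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
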