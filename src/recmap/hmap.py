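"""Case/control homozygosity mapping with sliding marker haplotypes.

Localises a recessive defect by scanning phased SNP-array genotypes for
windows in which affected individuals are homozygous for a shared
(identical-by-descent) haplotype while controls are not.  For every window
of ``window_size`` consecutive informative markers, each distinct haplotype
carried homozygously by at least one case yields a 2x2 contingency table

    ============  ==============  ===================
                  homozygous       any other genotype
    ------------  --------------  -------------------
    cases         a                b
    controls      c                d
    ============  ==============  ===================

tested with Fisher's exact test.  Adjacent qualifying windows (all cases
homozygous, no control homozygous) merge into the mapped haplotype; the
nearest informative markers outside that run bound the mapping interval.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PhasedGenotypeMatrix",
    "WindowTest",
    "MappingResult",
    "scan",
    "fisher_exact_2x2",
    "bonferroni_threshold",
    "extract_interval",
    "predict_status",
    "manhattan_frame",
]


class PhasedGenotypeMatrix:
    """Phased biallelic genotypes for a set of individuals.

    Parameters
    ----------
    individuals : sequence of str
        Ordered individual identifiers.
    markers : pandas.DataFrame
        One row per marker with columns ``chrom``, ``pos`` (1-based bp) and
        ``marker_id``, sorted by (chrom, pos).
    haplotypes : ndarray of shape (n_individuals, 2, n_markers)
        Alleles coded {0, 1}.  Missing genotypes are not permitted: the
        pipeline consumes phased, imputed data.
    """

    def __init__(self, individuals: Sequence[str], markers: pd.DataFrame,
                 haplotypes: np.ndarray):
        individuals = list(individuals)
        haplotypes = np.asarray(haplotypes, dtype=np.uint8)
        if haplotypes.ndim != 3 or haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n_individuals, 2, n_markers)")
        if haplotypes.shape[0] != len(individuals):
            raise ValueError("individual count does not match haplotype array")
        if haplotypes.shape[2] != len(markers):
            raise ValueError("marker count does not match haplotype array")
        if not set(np.unique(haplotypes)) <= {0, 1}:
            raise ValueError("alleles must be coded {0,1}; missing data not permitted")
        for col in ("chrom", "pos", "marker_id"):
            if col not in markers.columns:
                raise ValueError(f"marker table lacks column {col!r}")
        m = markers.reset_index(drop=True)
        order = m.sort_values(["chrom", "pos"], kind="stable").index
        if not np.array_equal(order.to_numpy(), np.arange(len(m))):
            raise ValueError("markers must be sorted by (chrom, pos)")
        if len(set(individuals)) != len(individuals):
            raise ValueError("duplicate individual identifiers")
        self.individuals = individuals
        self.markers = m
        self.haplotypes = haplotypes
        self._index = {iid: i for i, iid in enumerate(individuals)}

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def indices_of(self, ids: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._index[i] for i in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message detail
            raise KeyError(f"individual {exc.args[0]!r} not in genotype matrix") from None

    def allele_freq(self, individual_idx: np.ndarray | None = None) -> np.ndarray:
        """Frequency of allele 1 per marker, over all or a subset of individuals."""
        H = self.haplotypes if individual_idx is None else self.haplotypes[individual_idx]
        return H.reshape(-1, self.n_markers).mean(axis=0)

    def maf(self, individual_idx: np.ndarray | None = None) -> np.ndarray:
        p = self.allele_freq(individual_idx)
        return np.minimum(p, 1.0 - p)

    def dosage(self) -> np.ndarray:
        """(n_individuals, n_markers) count of allele 1."""
        return self.haplotypes.sum(axis=1)

    def subset_markers(self, marker_idx: np.ndarray) -> "PhasedGenotypeMatrix":
        return PhasedGenotypeMatrix(
            self.individuals,
            self.markers.iloc[marker_idx].reset_index(drop=True),
            self.haplotypes[:, :, marker_idx],
        )

    def exclude_chrom(self, chrom) -> "PhasedGenotypeMatrix":
        keep = np.flatnonzero((self.markers["chrom"] != chrom).to_numpy())
        return self.subset_markers(keep)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"PhasedGenotypeMatrix({self.n_individuals} individuals, "
                f"{self.n_markers} markers)")


@dataclass
class WindowTest:
    """One Fisher test of a candidate haplotype within one marker window."""

    chrom: object
    first_marker_index: int          # global index into the marker table
    window_size: int
    haplotype: str                   # allele string over the window, e.g. "01101..."
    a: int                           # cases homozygous for the haplotype
    b: int                           # cases with any other genotype
    c: int                           # controls homozygous
    d: int                           # controls with any other genotype
    p_value: float
    neg_log10_p: float
    marker_indices: np.ndarray = field(repr=False, default=None)
    pos_start: int = 0
    pos_end: int = 0


@dataclass
class MappingResult:
    """Merged haplotype run and the mapping interval that flanks it."""

    merged_haplotype_span: tuple | None   # (chrom, first_pos, last_pos, n_markers)
    interval: tuple | None                # (chrom, start_bp, end_bp)
    n_tests: int
    bonferroni_threshold_neglog10: float
    risk_haplotype: str | None = None
    marker_indices: np.ndarray | None = field(repr=False, default=None)
    diagnostics: str = ""

    @property
    def interval_width_bp(self) -> int | None:
        if self.interval is None:
            return None
        return self.interval[2] - self.interval[1]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Conventional two-sided definition: the sum of hypergeometric point
    probabilities, at fixed margins, no larger than that of the observed
    table.  A degenerate (all-zero margin) table returns p = 1.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    if a + b + c + d == 0:
        logger.info("all-zero 2x2 table: p = 1 by convention")
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Genome-wide significance threshold on the -log10 scale.

    ``n_tests`` is counted as the number of (window, haplotype) tests with at
    least one homozygous carrier among the cases.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(-math.log10(alpha / n_tests))


def scan(genotypes: PhasedGenotypeMatrix, cases: Iterable[str],
         controls: Iterable[str], window_size: int = 20,
         maf_floor: float = 0.01) -> list[WindowTest]:
    """Sliding-haplotype homozygosity scan.

    Windows of ``window_size`` informative markers (MAF > ``maf_floor``
    across cases+controls), incremented by one marker within each
    chromosome.  An individual is homozygous for a haplotype when its two
    phased alleles are identical across the window and equal that haplotype;
    heterozygous carriers count as "any other genotype".  One test is
    emitted per (window, distinct haplotype homozygous in >= 1 case).
    """
    cases = list(cases)
    controls = list(controls)
    if set(cases) & set(controls):
        raise ValueError("cases and controls overlap")
    ci = genotypes.indices_of(cases)
    ni = genotypes.indices_of(controls)
    maf = genotypes.maf(np.concatenate([ci, ni]))
    keep = np.flatnonzero(maf > maf_floor)
    n_cases, n_controls = len(ci), len(ni)
    tests: list[WindowTest] = []
    pos = genotypes.markers["pos"].to_numpy()
    chroms = genotypes.markers["chrom"].to_numpy()
    for chrom in pd.unique(genotypes.markers["chrom"]):
        cols = keep[chroms[keep] == chrom]
        if len(cols) < window_size:
            logger.warning("chromosome %s has %d informative markers < window %d; skipped",
                           chrom, len(cols), window_size)
            continue
        Hc = genotypes.haplotypes[ci][:, :, cols]
        Hn = genotypes.haplotypes[ni][:, :, cols]
        for s in range(len(cols) - window_size + 1):
            wc = Hc[:, :, s:s + window_size]
            hom_case = (wc[:, 0, :] == wc[:, 1, :]).all(axis=1)
            if not hom_case.any():
                continue
            case_counts = Counter(h.tobytes() for h in wc[hom_case, 0, :])
            wn = Hn[:, :, s:s + window_size]
            hom_ctrl = (wn[:, 0, :] == wn[:, 1, :]).all(axis=1)
            ctrl_counts = Counter(h.tobytes() for h in wn[hom_ctrl, 0, :])
            widx = cols[s:s + window_size]
            for key, a in case_counts.items():
                c = ctrl_counts.get(key, 0)
                p = fisher_exact_2x2(a, n_cases - a, c, n_controls - c)
                hap = np.frombuffer(key, dtype=np.uint8)
                tests.append(WindowTest(
                    chrom=chrom,
                    first_marker_index=int(widx[0]),
                    window_size=window_size,
                    haplotype="".join(map(str, hap)),
                    a=int(a), b=int(n_cases - a), c=int(c), d=int(n_controls - c),
                    p_value=p,
                    neg_log10_p=float(-math.log10(p)) if p > 0 else math.inf,
                    marker_indices=widx.copy(),
                    pos_start=int(pos[widx[0]]),
                    pos_end=int(pos[widx[-1]]),
                ))
    return tests


def _merge_runs(windows: list[WindowTest]) -> list[tuple]:
    """Merge overlapping qualifying windows into maximal marker runs.

    Windows are drawn from the same ordered informative-marker subsequence,
    so two windows on one chromosome share markers iff their global index
    ranges intersect.  Returns (chrom, sorted union of marker indices,
    member windows) per run.
    """
    runs = []
    for chrom in sorted({w.chrom for w in windows}, key=str):
        ws = sorted((w for w in windows if w.chrom == chrom),
                    key=lambda w: w.first_marker_index)
        cur_idx = set(ws[0].marker_indices.tolist())
        cur_members = [ws[0]]
        cur_last = int(ws[0].marker_indices[-1])
        for w in ws[1:]:
            if w.first_marker_index <= cur_last:
                cur_idx.update(w.marker_indices.tolist())
                cur_last = max(cur_last, int(w.marker_indices[-1]))
                cur_members.append(w)
            else:
                runs.append((chrom, np.array(sorted(cur_idx)), cur_members))
                cur_idx = set(w.marker_indices.tolist())
                cur_members = [w]
                cur_last = int(w.marker_indices[-1])
        runs.append((chrom, np.array(sorted(cur_idx)), cur_members))
    return runs


def extract_interval(tests: Sequence[WindowTest], genotypes: PhasedGenotypeMatrix,
                     cases: Iterable[str], controls: Iterable[str],
                     alpha: float = 0.05, maf_floor: float = 0.01) -> MappingResult:
    """Merge qualifying windows and derive the mapping interval.

    Qualifying windows have every case homozygous for the tested haplotype
    and no control homozygous.  Overlapping qualifying windows merge into a
    maximal marker run; if several disjoint runs exist the one containing
    the smallest p-value is mapped (others are reported in diagnostics).
    The interval is bounded by the most proximal informative markers outside
    the run; at a chromosome edge it is truncated at the run boundary.
    """
    tests = list(tests)
    n_tests = len(tests)
    thr = bonferroni_threshold(alpha, max(n_tests, 1))
    qualifying = [t for t in tests if t.b == 0 and t.c == 0 and t.a > 0]
    if not qualifying:
        return MappingResult(None, None, n_tests, thr,
                             diagnostics="no window with all cases homozygous and "
                                         "zero homozygous controls")
    runs = _merge_runs(qualifying)
    # Qualifying windows tie on p when margins coincide, so rank runs by
    # their best p first and, at exact ties, by run length (the mapped
    # signal is the longest plateau of best windows).
    run = min(runs, key=lambda r: (min(t.p_value for t in r[2]), -len(r[1])))
    chrom, run_idx, members = run
    diag = ""
    if len(runs) > 1:
        others = [(r[0], len(r[1])) for r in runs if r is not run]
        diag = f"additional qualifying runs not mapped: {others}"
        logger.warning("%s", diag)

    pos = genotypes.markers["pos"].to_numpy()
    chroms = genotypes.markers["chrom"].to_numpy()
    # Informative markers on this chromosome, recomputed exactly as the
    # scan selects them (``maf_floor`` must match the scan's).
    ci = genotypes.indices_of(list(cases))
    ni = genotypes.indices_of(list(controls))
    maf = genotypes.maf(np.concatenate([ci, ni]))
    informative = np.flatnonzero((maf > maf_floor) & (chroms == chrom))
    first, last = int(run_idx[0]), int(run_idx[-1])
    before = informative[informative < first]
    after = informative[informative > last]
    start = int(pos[before[-1]]) if len(before) else int(pos[first])
    end = int(pos[after[0]]) if len(after) else int(pos[last])
    if not len(before) or not len(after):
        logger.warning("merged run abuts a chromosome edge; interval truncated "
                       "at the run boundary")
        diag = (diag + "; " if diag else "") + "interval truncated at chromosome edge"

    # Shared case haplotype over the run: all cases are homozygous for it.
    risk = genotypes.haplotypes[ci[0], 0, run_idx]
    span = (chrom, int(pos[first]), int(pos[last]), len(run_idx))
    assert (chroms[run_idx] == chrom).all()
    return MappingResult(
        merged_haplotype_span=span,
        interval=(chrom, start, end),
        n_tests=n_tests,
        bonferroni_threshold_neglog10=thr,
        risk_haplotype="".join(map(str, risk)),
        marker_indices=run_idx,
        diagnostics=diag,
    )


def top_windows(tests: Sequence[WindowTest],
                rel_tol: float = 1e-9) -> list[WindowTest]:
    """Windows attaining the scan's minimal p-value.

    Fisher p-values tie exactly whenever two windows share the same
    contingency table, so the scan's "top window" is generally a plateau of
    adjacent windows spanning the shared homozygous segment; the full
    plateau is returned.
    """
    tests = list(tests)
    if not tests:
        return []
    pmin = min(t.p_value for t in tests)
    return [t for t in tests if t.p_value <= pmin * (1.0 + rel_tol)]


def predict_status(individual_haplotypes: np.ndarray, risk_haplotype: str) -> int:
    """Risk-haplotype dosage {0,1,2} from the two phased haplotypes over the run.

    Parameters
    ----------
    individual_haplotypes : ndarray of shape (2, n_run_markers)
    risk_haplotype : allele string over the merged-run markers
    """
    risk = np.array([int(x) for x in risk_haplotype], dtype=np.uint8)
    H = np.asarray(individual_haplotypes, dtype=np.uint8)
    if H.shape != (2, len(risk)):
        raise ValueError("haplotypes must have shape (2, n_run_markers)")
    return int((H == risk).all(axis=1).sum())


def tests_to_frame(tests: Sequence[WindowTest]) -> pd.DataFrame:
    """Tabulate scan results (Manhattan-plot-ready)."""
    return pd.DataFrame({
        "chrom": [t.chrom for t in tests],
        "pos_start": [t.pos_start for t in tests],
        "pos_end": [t.pos_end for t in tests],
        "haplotype": [t.haplotype for t in tests],
        "a": [t.a for t in tests],
        "b": [t.b for t in tests],
        "c": [t.c for t in tests],
        "d": [t.d for t in tests],
        "p_value": [t.p_value for t in tests],
        "neg_log10_p": [t.neg_log10_p for t in tests],
    })


def manhattan_frame(tests: Sequence[WindowTest]) -> pd.DataFrame:
    """Best -log10(p) per window start, for plotting."""
    df = tests_to_frame(tests)
    return (df.groupby(["chrom", "pos_start"], as_index=False)["neg_log10_p"]
              .max())


def manhattan_plot(tests: Sequence[WindowTest], path, threshold: float | None = None):
    """Write a simple Manhattan plot PNG of the scan."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = manhattan_frame(tests)
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    for i, (chrom, sub) in enumerate(df.groupby("chrom", sort=True)):
        ax.scatter(sub["pos_start"] + offset, sub["neg_log10_p"], s=4,
                   color="C0" if i % 2 == 0 else "C1", label=None)
        offset += sub["pos_start"].max() + 1
    if threshold is not None:
        ax.axhline(threshold, color="red", lw=0.8, ls="--")
    ax.set_xlabel("genome position")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
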