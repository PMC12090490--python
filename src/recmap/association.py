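"""Mixed-linear-model association for heterozygote effects, with GRM,
effect scaling in genetic-standard-deviation units, and multiple-testing
control.

The single-variant model is

    y = 1 mu + x b + u + e,   u ~ N(0, G sigma_u^2),   e ~ N(0, I sigma_e^2)

where y holds phenotypes pre-adjusted for non-genetic effects, x is the
carrier dosage (0/1 — homozygotes are absent from any phenotyped cohort of
a fully penetrant lethal), and G is the VanRaden method-1 genomic
relationship matrix built without markers from the target chromosome.
Variance components come from REML under the null model (no x); the fixed
effects are then estimated by generalised least squares at those
components, with a two-sided Wald test for b.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "MlmaResult",
    "grm",
    "grm_eig",
    "mlma",
    "effect_in_gsd",
    "bh_qvalues",
]


def grm(genotypes, exclude_chrom=None) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    ``genotypes`` is a :class:`~recmap.hmap.PhasedGenotypeMatrix` or a
    (n_individuals, n_markers) dosage array.  Markers on ``exclude_chrom``
    are removed first; monomorphic markers are dropped with a warning.
    With W the column-centred dosage matrix (w = g - 2p at sample allele
    frequencies p), G = W W' / (2 sum p(1-p)).
    """
    if hasattr(genotypes, "dosage"):
        g = genotypes.exclude_chrom(exclude_chrom) if exclude_chrom is not None \
            else genotypes
        X = g.dosage().astype(float)
    else:
        if exclude_chrom is not None:
            raise ValueError("exclude_chrom requires a PhasedGenotypeMatrix")
        X = np.asarray(genotypes, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two individuals")
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.all():
        logger.warning("dropping %d monomorphic markers", int((~poly).sum()))
        X, p = X[:, poly], p[poly]
    if X.shape[1] == 0:
        raise ValueError("no polymorphic markers left")
    W = X - 2.0 * p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    return (W @ W.T) / denom


def grm_eig(G: np.ndarray, tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a (PSD) relationship matrix, reusable across
    repeated :func:`mlma` calls on the same cohort."""
    G = np.asarray(G, dtype=float)
    if not np.allclose(G, G.T, atol=1e-8):
        raise ValueError("relationship matrix must be symmetric")
    vals, vecs = np.linalg.eigh(G)
    if vals.min() < -tol * max(vals.max(), 1.0):
        raise ValueError("relationship matrix is not positive semidefinite")
    return np.clip(vals, 0.0, None), vecs


@dataclass
class MlmaResult:
    b: float
    se: float
    p_value: float
    mu: float
    sigma_u2: float
    sigma_e2: float
    h2: float


def _reml_h2(yr: np.ndarray, Xr: np.ndarray, d: np.ndarray) -> tuple[float, float]:
    """Profile REML over heritability on the rotated (eigen) axes.

    With V = sigma_p^2 (h2 D + (1-h2) I) in the rotated basis, sigma_p^2
    profiles out analytically; a bounded 1-D derivative-free optimisation
    over h2 gives an exact, deterministic fit.
    """
    n, k = Xr.shape

    def nll(h2: float) -> float:
        w = h2 * d + (1.0 - h2)
        Xw = Xr / w[:, None]
        A = Xr.T @ Xw
        beta = np.linalg.solve(A, Xw.T @ yr)
        r = yr - Xr @ beta
        rss = float(np.sum(r * r / w))
        s2 = rss / (n - k)
        sign, logdetA = np.linalg.slogdet(A)
        return 0.5 * ((n - k) * math.log(s2) + float(np.sum(np.log(w)))
                      + logdetA + (n - k))

    res = optimize.minimize_scalar(nll, bounds=(1e-6, 1.0 - 1e-6),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    h2 = float(res.x)
    # recompute sigma_p^2 at the optimum
    w = h2 * d + (1.0 - h2)
    Xw = Xr / w[:, None]
    beta = np.linalg.solve(Xr.T @ Xw, Xw.T @ yr)
    r = yr - Xr @ beta
    s2 = float(np.sum(r * r / w)) / (n - k)
    return h2, s2


def mlma(y, x, G: np.ndarray | None = None, *,
         eig: tuple[np.ndarray, np.ndarray] | None = None,
         h2: float | None = None) -> MlmaResult:
    """Single-variant mixed-model association.

    Pass either ``G`` or its precomputed ``eig`` (from :func:`grm_eig`;
    reusing it makes repeated tests on one cohort cheap).  ``h2`` fixes the
    heritability instead of REML-estimating it under the null — ``h2=0``
    collapses the model to ordinary least squares.  Returns the allele
    effect b, its standard error, the two-sided Wald p, and the variance
    components.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    n = len(y)
    if len(x) != n:
        raise ValueError("y and x lengths differ")
    if float(np.var(y)) == 0.0:
        raise ValueError("phenotype has zero variance")
    if eig is None:
        if G is None:
            raise ValueError("pass G or eig")
        if G.shape != (n, n):
            raise ValueError("G dimension does not match y")
        eig = grm_eig(G)
    d, U = eig
    yr = U.T @ y
    ones_r = U.T @ np.ones(n)
    if h2 is None:
        h2_hat, s2 = _reml_h2(yr, ones_r[:, None], d)
    else:
        if not 0.0 <= h2 < 1.0 + 1e-12:
            raise ValueError("h2 must lie in [0,1)")
        h2_hat = float(min(h2, 1.0 - 1e-9))
        w0 = h2_hat * d + (1.0 - h2_hat)
        b0 = float(np.sum(ones_r * yr / w0) / np.sum(ones_r**2 / w0))
        s2 = float(np.sum((yr - ones_r * b0) ** 2 / w0)) / (n - 1)

    # GLS at the null-model heritability; the residual scale is
    # re-estimated from the full-model residuals so that h2 = 0 collapses
    # exactly to ordinary least squares.
    w = h2_hat * d + (1.0 - h2_hat)
    Xr = np.column_stack([ones_r, U.T @ x])
    Xw = Xr / w[:, None]
    A = Xr.T @ Xw
    cov = np.linalg.inv(A)
    beta = cov @ (Xw.T @ yr)
    resid = yr - Xr @ beta
    s2_full = float(np.sum(resid * resid / w)) / (n - Xr.shape[1])
    se = float(np.sqrt(cov[1, 1] * s2_full))
    b = float(beta[1])
    z = b / se
    # t reference with residual df: indistinguishable from the normal Wald
    # test at cohort sizes, exact at the OLS collapse
    p = float(2.0 * stats.t.sf(abs(z), df=n - Xr.shape[1]))
    return MlmaResult(b=b, se=se, p_value=p, mu=float(beta[0]),
                      sigma_u2=h2_hat * s2, sigma_e2=(1.0 - h2_hat) * s2,
                      h2=h2_hat)


def effect_in_gsd(b: float, gsd: float) -> float:
    """|allele effect| as a fraction of the trait's genetic SD."""
    if gsd <= 0:
        raise ValueError("genetic standard deviation must be positive")
    return abs(b) / gsd


def bh_qvalues(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order.

    q(k) = min over j >= k of p(j) * n / j, capped at 1 (ties share the
    smaller q).  The hypothesis family is exactly the p-values passed in —
    callers choose the family.  Implemented via statsmodels' fdr_bh
    corrected p-values, which realise the same step-up.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def association_table(results: dict[str, MlmaResult],
                      counts: dict[str, tuple[int, int]] | None = None,
                      gsd: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-trait association summary with BH q-values over the trait family."""
    traits = list(results)
    p = [results[t].p_value for t in traits]
    q = bh_qvalues(p)
    df = pd.DataFrame({
        "trait": traits,
        "b_effect": [results[t].b for t in traits],
        "se": [results[t].se for t in traits],
        "p_value": p,
        "q_value": q,
    })
    if counts is not None:
        df["n_wildtype"] = [counts[t][0] for t in traits]
        df["n_het"] = [counts[t][1] for t in traits]
    if gsd is not None:
        df["effect_in_gsd"] = [effect_in_gsd(results[t].b, gsd[t]) for t in traits]
    return df
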