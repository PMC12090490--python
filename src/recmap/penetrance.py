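"""Mating-type mortality contrasts and penetrance arithmetic.

Mating types are written sire x maternal-grandsire in risk-allele dosage
(1x1, 1x0, 0x1, 0x0): when dams are ungenotyped, the maternal grandsire's
genotype is the available proxy.  Period mortality rates are contrasted
against 0x0 matings under the one-way fixed-effect model

    y_ij = mu + m_j + e_ij

on 0/100 death indicators (percent scale), so group means print directly
as percentages.  Under complete penetrance of homozygote lethality, the
expected excess mortality in 1x1 matings has the closed form

    (1 / (4 (2 - fA))) * (1 - mu)

where fA is the population risk-allele frequency and mu the baseline
mortality of the period: a surviving daughter of a heterozygous bull is
heterozygous with probability 1/(2 - fA) (homozygous daughters having died),
and a homozygous calf requires both her and the heterozygous sire to
transmit the allele (x 1/2 each).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .simulate import PERIODS

logger = logging.getLogger(__name__)

__all__ = [
    "ContrastResult",
    "PenetranceCheck",
    "mortality_rate",
    "fit_mating_model",
    "expected_increase",
    "dam_genotype_probs",
    "penetrance_check",
    "periods_at_risk",
]

REFERENCE = "0x0"
#: The 0-14 d window combines the first two periods on the 0-2 d at-risk base.
COMBINED = {"0-14": ("0-2", "3-14")}


@dataclass
class ContrastResult:
    """One mating type's period mortality and its contrast against 0x0."""

    period: str
    mating_type: str
    n: int
    raw_mean: float                     # percent
    diff_vs_00: float | None            # percent; None for the reference group
    se: float | None                    # percent
    p_value: float | None
    q_values: dict = field(default_factory=dict)


def mortality_rate(deaths: int, at_risk: int) -> float:
    """Deaths during a period over calves present at its beginning."""
    if at_risk <= 0:
        raise ValueError("mortality rate undefined: no calves at risk")
    if not 0 <= deaths <= at_risk:
        raise ValueError("need 0 <= deaths <= at_risk")
    return deaths / at_risk


def periods_at_risk(table: pd.DataFrame, period: str) -> pd.DataFrame:
    """Calves at risk at the start of ``period``, with their 0/1 outcome.

    ``table`` is calf-level with columns ``mating_type`` and one column per
    period holding {"yes", "no", "censored"}.  A calf dead in an earlier
    period is not at risk; censored calves are excluded from the period.
    Combined periods ("0-14") count death in any constituent period on the
    at-risk base of the first.
    """
    parts = COMBINED.get(period, (period,))
    for p in parts:
        if p not in table.columns:
            raise ValueError(f"table lacks period column {p!r}")
    earlier = [p for p in PERIODS if PERIODS.index(p) < PERIODS.index(parts[0])]
    at_risk = table.copy()
    for p in earlier:
        if p in at_risk.columns:
            at_risk = at_risk[at_risk[p] == "no"]
    ok = (at_risk[list(parts)] != "censored").all(axis=1)
    at_risk = at_risk[ok]
    died = (at_risk[list(parts)] == "yes").any(axis=1)
    return pd.DataFrame({"mating_type": at_risk["mating_type"].to_numpy(),
                         "died": died.astype(int).to_numpy()})


def fit_mating_model(table: pd.DataFrame, period: str | None = None
                     ) -> list[ContrastResult]:
    """One-way fixed-effect fit of period mortality on mating type.

    ``table`` is either calf-level with period columns (pass ``period``) or
    already reduced to columns ``mating_type`` and ``died`` (0/1).  Death
    indicators are scaled to 0/100 so that means, contrasts and standard
    errors are in percent.  With mating type as the only factor, each
    contrast against 0x0 equals the raw-mean difference; its standard error
    uses the pooled residual variance, and the p-value is a two-sided
    t-test.
    """
    import statsmodels.formula.api as smf

    df = periods_at_risk(table, period) if period is not None else table.copy()
    if "died" not in df.columns or "mating_type" not in df.columns:
        raise ValueError("need columns mating_type and died")
    types = df["mating_type"].unique()
    if REFERENCE not in types:
        raise ValueError(f"reference mating type {REFERENCE!r} absent")
    if len(types) < 2:
        raise ValueError("need at least two mating types")
    df = df.assign(y=df["died"].astype(float) * 100.0)
    fit = smf.ols(f"y ~ C(mating_type, Treatment('{REFERENCE}'))", data=df).fit()

    results = []
    grouped = df.groupby("mating_type")["y"]
    label = period if period is not None else ""
    for mt in sorted(types, reverse=True):
        n = int(grouped.count()[mt])
        mean = float(grouped.mean()[mt])
        if mt == REFERENCE:
            results.append(ContrastResult(label, mt, n, mean, None, None, None))
            continue
        term = f"C(mating_type, Treatment('{REFERENCE}'))[T.{mt}]"
        results.append(ContrastResult(
            label, mt, n, mean,
            diff_vs_00=float(fit.params[term]),
            se=float(fit.bse[term]),
            p_value=float(fit.pvalues[term]),
        ))
    return results


def contrasts_to_frame(results: list[ContrastResult]) -> pd.DataFrame:
    """Table-shaped summary (percent values at full precision)."""
    return pd.DataFrame({
        "period": [r.period for r in results],
        "mating_type": [r.mating_type for r in results],
        "n": [r.n for r in results],
        "raw_mean_pct": [r.raw_mean for r in results],
        "diff_pct": [r.diff_vs_00 for r in results],
        "se_pct": [r.se for r in results],
        "p_value": [r.p_value for r in results],
    })


def expected_increase(fA: float, mu: float) -> float:
    """Expected excess mortality of 1x1 matings under complete penetrance."""
    if not 0.0 <= fA < 1.0:
        raise ValueError("fA must lie in [0,1)")
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must lie in [0,1]")
    return (1.0 / (4.0 * (2.0 - fA))) * (1.0 - mu)


def dam_genotype_probs(fA: float) -> tuple[float, float]:
    """Genotype of a surviving daughter of a heterozygous bull.

    Returns (P(wild-type), P(heterozygous)); the homozygous class is
    removed by perinatal lethality and the remaining probabilities are
    renormalised.  They sum to 1 for every fA.
    """
    if not 0.0 <= fA < 1.0:
        raise ValueError("fA must lie in [0,1)")
    denom = 2.0 * (1.0 - 0.5 * fA)
    return ((1.0 - fA) / denom, 1.0 / denom)


@dataclass
class PenetranceCheck:
    """Observed/expected mortality vs case-registration comparison."""

    ratio_observed_expected: float
    registration_proportion: float
    observed_counts: tuple            # (k, n-k) out of n = reported
    registered_counts: tuple
    fisher_p: float
    chisq_stat: float
    chisq_p: float


def penetrance_check(observed_increase: float, expected: float,
                     reported: int, registered: int) -> PenetranceCheck:
    """Compare the realised fraction of the expected mortality excess with
    the fraction of cases officially registered.

    Both proportions are converted to integer count pairs out of
    ``reported`` cases (rounded).  Two p-values are returned for their
    comparison — Pearson chi-squared goodness of fit (df = 1, registered
    proportions as expected) and Fisher's exact 2x2 — because the two
    conventions can differ materially at such small counts; no silent
    choice is made between them.
    """
    if expected == 0:
        raise ValueError("expected increase is zero: ratio undefined")
    if not 0 <= registered <= reported:
        raise ValueError("need 0 <= registered <= reported")
    ratio = observed_increase / expected
    reg = registered / reported
    k_obs = int(round(ratio * reported))
    obs = (k_obs, reported - k_obs)
    regc = (registered, reported - registered)
    expected_counts = (reg * reported, (1 - reg) * reported)
    # a zero-expected cell contributes nothing when the observed count is
    # also zero, and makes the statistic infinite otherwise
    chisq = sum(0.0 if e == 0 and o == 0 else
                (float("inf") if e == 0 else (o - e) ** 2 / e)
                for o, e in zip(obs, expected_counts))
    chisq_p = float(stats.chi2.sf(chisq, df=1))
    fisher_p = float(stats.fisher_exact([list(obs), list(regc)])[1])
    return PenetranceCheck(
        ratio_observed_expected=ratio,
        registration_proportion=reg,
        observed_counts=obs,
        registered_counts=regc,
        fisher_p=fisher_p,
        chisq_stat=float(chisq),
        chisq_p=chisq_p,
    )
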