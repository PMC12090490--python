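"""Staged candidate-variant filtering for sequenced affected individuals.

The candidate causal variant of a breed-specific recessive defect must be
(i) inside the mapping interval, (ii) homozygous for the alternate allele
in every sequenced case, and (iii) absent from control panels: first the
within-breed panel of haplotype-verified non-carriers, then the multi-breed
panel (recessive defects are, with rare exceptions, breed-specific).
Control-panel absence is consumed as precomputed presence flags; "not
segregating at all" means zero alternate alleles, so a heterozygous control
also disqualifies a variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["FilterTrace", "SV", "filter_candidates", "sv_concordance"]

GENOTYPES = {"hom_ref", "het", "hom_alt", "missing"}

#: Supplementary-table dialect column names accepted on input.
S2_RENAMES = {
    "Chr": "chrom",
    "Pos": "pos",
    "Ref": "ref",
    "Alt": "alt",
    "Type": "type",
    "Present_in_39_Aubrac_controls": "present_in_breed_controls",
    "Present_in_1828_controls_from_other_breeds": "present_in_other_breeds",
}


@dataclass
class FilterTrace:
    """Per-stage candidate counts (monotone non-increasing) and survivors."""

    n_input: int
    n_in_interval: int
    n_hom_all_cases: int
    n_after_breed_controls: int
    n_after_all_controls: int
    survivors: list = field(default_factory=list)
    n_missing_genotype: int = 0
    counts_by_type: dict = field(default_factory=dict)

    def __post_init__(self):
        chain = (self.n_input, self.n_in_interval, self.n_hom_all_cases,
                 self.n_after_breed_controls, self.n_after_all_controls)
        if any(b > a for a, b in zip(chain, chain[1:])):
            raise ValueError(f"stage counts must be non-increasing: {chain}")


def _normalise(variants: pd.DataFrame) -> pd.DataFrame:
    df = variants.rename(columns=S2_RENAMES).copy()
    required = ["chrom", "pos", "ref", "alt",
                "present_in_breed_controls", "present_in_other_breeds"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"variant table lacks columns {missing}")
    keys = df[["chrom", "pos", "ref", "alt"]].astype(str).agg(":".join, axis=1)
    if keys.duplicated().any():
        raise ValueError("duplicate (chrom,pos,ref,alt) keys in variant table")
    for col in ("present_in_breed_controls", "present_in_other_breeds"):
        if df[col].dtype == object:
            df[col] = df[col].map(
                {"yes": True, "no": False, "Yes": True, "No": False,
                 "True": True, "False": False, True: True, False: False})
        df[col] = df[col].astype(bool)
    return df


def filter_candidates(variants: pd.DataFrame, interval: tuple,
                      case_ids) -> FilterTrace:
    """Apply the four filter stages in order and record per-stage counts.

    ``variants`` columns: chrom, pos, ref, alt, optional type, one
    ``genotype_<case>`` column per sequenced case with values in
    {hom_ref, het, hom_alt, missing}, and the two control-presence flags
    (Supplementary-table dialect column names are accepted).  A variant
    with a missing genotype in any case fails the homozygosity stage
    (logged).  Surviving variant keys are (chrom, pos, ref, alt) tuples.
    """
    case_ids = list(case_ids)
    df = _normalise(variants)
    gcols = [f"genotype_{c}" for c in case_ids]
    missing_cols = [c for c in gcols if c not in df.columns]
    if missing_cols:
        raise ValueError(f"variant table lacks case genotype columns {missing_cols}")
    bad = set(pd.unique(df[gcols].to_numpy().ravel())) - GENOTYPES
    if bad:
        raise ValueError(f"unknown genotype codes {sorted(bad)}")
    chrom, start, end = interval
    if start > end:
        raise ValueError("malformed interval: start > end")
    n_input = len(df)
    if n_input == 0:
        return FilterTrace(0, 0, 0, 0, 0, [])

    stage1 = df[(df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] <= end)]
    hom = (stage1[gcols] == "hom_alt").all(axis=1)
    n_missing = int((stage1[gcols] == "missing").any(axis=1).sum())
    if n_missing:
        logger.info("%d in-interval variants had a missing case genotype "
                    "and fail the homozygosity stage", n_missing)
    stage2 = stage1[hom]
    stage3 = stage2[~stage2["present_in_breed_controls"]]
    stage4 = stage3[~stage3["present_in_other_breeds"]]

    survivors = [tuple(r) for r in
                 stage4[["chrom", "pos", "ref", "alt"]].itertuples(index=False)]
    by_type = {}
    if "type" in df.columns:
        by_type = {
            "input": df["type"].value_counts().to_dict(),
            "hom_all_cases": stage2["type"].value_counts().to_dict(),
            "after_all_controls": stage4["type"].value_counts().to_dict(),
        }
    return FilterTrace(
        n_input=n_input,
        n_in_interval=len(stage1),
        n_hom_all_cases=len(stage2),
        n_after_breed_controls=len(stage3),
        n_after_all_controls=len(stage4),
        survivors=survivors,
        n_missing_genotype=n_missing,
        counts_by_type=by_type,
    )


@dataclass(frozen=True)
class SV:
    """A structural-variant call from one detection tool."""

    chrom: str
    start: int
    end: int
    type: str
    individual: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _reciprocal_overlap(a: SV, b: SV) -> float:
    ov = min(a.end, b.end) - max(a.start, b.start) + 1
    if ov <= 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def sv_concordance(calls_by_tool: dict, min_overlap: float = 0.70) -> list[tuple]:
    """Consensus structural variants across detection tools.

    A call is kept when at least two tools report an interval of the same
    type in the same individual with reciprocal overlap >= ``min_overlap``
    (overlap/length >= the threshold for BOTH intervals — "mutual overlap"
    read reciprocally).  Zero- or negative-length calls are rejected with a
    diagnostic.  Returns (SV, supporting tools) pairs, keeping each tool's
    concordant call once.
    """
    clean: dict[str, list[SV]] = {}
    for tool, calls in calls_by_tool.items():
        kept = []
        for sv in calls:
            if not isinstance(sv, SV):
                sv = SV(**sv)
            if sv.length <= 0:
                logger.warning("tool %s: zero/negative-length SV %s rejected",
                               tool, sv)
                continue
            kept.append(sv)
        clean[tool] = kept
    out = []
    tools = list(clean)
    for i, tool in enumerate(tools):
        for sv in clean[tool]:
            support = {tool}
            for other in tools:
                if other == tool:
                    continue
                for cand in clean[other]:
                    if (cand.chrom == sv.chrom and cand.type == sv.type
                            and cand.individual == sv.individual
                            and _reciprocal_overlap(sv, cand) >= min_overlap):
                        support.add(other)
                        break
            if len(support) >= 2:
                out.append((sv, sorted(support)))
    return out
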