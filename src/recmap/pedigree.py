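"""Ancestor sets and expected genetic contributions from pedigree records.

The expected genetic contribution of an ancestor ``a`` to an individual
``i`` is the probability that a gene picked at random from ``i``'s
autosomal genome descends from ``a`` through any path:

    c(i) = 1                        if i = a
    c(i) = (c(sire) + c(dam)) / 2   otherwise, unknown parents contributing 0

The contribution to a population is the mean of c(i) over its members.
Ranking ancestors by the ratio of their contributions to an affected case
group versus a large control group flags the putative founder of a
recessive defect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

UNKNOWN = "0"

__all__ = [
    "Pedigree",
    "ContributionReport",
    "ancestor_set",
    "common_ancestors",
    "genetic_contribution",
    "contribution_ratio",
    "rank_contribution_ratios",
]


class Pedigree:
    """Parent lookup over pedigree records.

    Accepts a DataFrame with columns ``id``, ``sire``, ``dam`` (optionally
    ``sex``, ``birth_year``); ``"0"`` (or NA) marks an unknown parent.  The
    parentage graph must be acyclic: no individual may be its own ancestor.
    """

    def __init__(self, records: pd.DataFrame):
        for col in ("id", "sire", "dam"):
            if col not in records.columns:
                raise ValueError(f"pedigree lacks column {col!r}")
        ids = records["id"].astype(str)
        if ids.duplicated().any():
            raise ValueError("duplicate individual ids in pedigree")
        self.parents: dict[str, tuple[str | None, str | None]] = {}
        for row in records.itertuples(index=False):
            s = None if pd.isna(row.sire) or str(row.sire) == UNKNOWN else str(row.sire)
            d = None if pd.isna(row.dam) or str(row.dam) == UNKNOWN else str(row.dam)
            self.parents[str(row.id)] = (s, d)
        self._check_acyclic()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        return cls(frame)

    def __contains__(self, iid: str) -> bool:
        return iid in self.parents

    def __len__(self) -> int:
        return len(self.parents)

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}           # 0 visiting, 1 done
        for start in self.parents:
            if start in state:
                continue
            stack = [(start, iter(self._known_parents(start)))]
            state[start] = 0
            while stack:
                node, it = stack[-1]
                advanced = False
                for parent in it:
                    if state.get(parent) == 0:
                        raise ValueError(
                            f"pedigree contains a cycle through {parent!r}")
                    if parent not in state and parent in self.parents:
                        state[parent] = 0
                        stack.append((parent, iter(self._known_parents(parent))))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 1
                    stack.pop()

    def _known_parents(self, iid: str):
        s, d = self.parents.get(iid, (None, None))
        return [p for p in (s, d) if p is not None]


def _as_pedigree(pedigree) -> Pedigree:
    return pedigree if isinstance(pedigree, Pedigree) else Pedigree(pedigree)


@dataclass
class ContributionReport:
    ancestor: str
    contrib_cases: float
    contrib_controls: float
    ratio: float | None                  # None when the control contribution is 0


def ancestor_set(iid: str, pedigree) -> set[str]:
    """All known ancestors of ``iid`` (transitive closure; excludes ``iid``)."""
    ped = _as_pedigree(pedigree)
    if iid not in ped:
        raise KeyError(f"individual {iid!r} not in pedigree")
    out: set[str] = set()
    stack = list(ped._known_parents(iid))
    while stack:
        a = stack.pop()
        if a in out:
            continue
        out.add(a)
        if a in ped:
            stack.extend(ped._known_parents(a))
    return out


def common_ancestors(case_ids: Iterable[str], pedigree) -> dict[str, int]:
    """Count, per ancestor, the cases whose sire AND dam both descend from it.

    A parent itself counts as descending from itself.  Cases without any
    recorded parent are excluded (logged).  Returns a mapping sorted by
    descending count.
    """
    ped = _as_pedigree(pedigree)
    counts: dict[str, int] = {}
    for cid in case_ids:
        if cid not in ped:
            raise KeyError(f"case {cid!r} not in pedigree")
        s, d = ped.parents[cid]
        if s is None and d is None:
            logger.warning("case %s has no recorded parents; excluded", cid)
            continue
        side_s = ({s} | ancestor_set(s, ped)) if s is not None and s in ped else \
            ({s} if s is not None else set())
        side_d = ({d} | ancestor_set(d, ped)) if d is not None and d in ped else \
            ({d} if d is not None else set())
        for anc in side_s & side_d:
            counts[anc] = counts.get(anc, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


def genetic_contribution(ancestor: str, population: Iterable[str],
                         pedigree) -> float:
    """Expected genetic contribution of ``ancestor`` to ``population``.

    Exact recursion with memoisation; an unknown parent contributes 0 (its
    gene mass is booked to "unknown").
    """
    ped = _as_pedigree(pedigree)
    population = list(population)
    if not population:
        raise ValueError("population is empty")
    if ancestor not in ped:
        raise KeyError(f"ancestor {ancestor!r} not in pedigree")
    memo: dict[str, float] = {ancestor: 1.0}

    def c(iid: str) -> float:
        if iid in memo:
            return memo[iid]
        # iterative post-order to avoid recursion limits on deep pedigrees
        stack = [iid]
        while stack:
            node = stack[-1]
            if node in memo:
                stack.pop()
                continue
            s, d = ped.parents.get(node, (None, None))
            pending = [p for p in (s, d)
                       if p is not None and p in ped and p not in memo]
            if pending:
                stack.extend(pending)
                continue
            cs = memo.get(s, 0.0) if s is not None else 0.0
            cd = memo.get(d, 0.0) if d is not None else 0.0
            memo[node] = 0.5 * (cs + cd)
            stack.pop()
        return memo[iid]

    total = 0.0
    for iid in population:
        if iid not in ped:
            raise KeyError(f"population member {iid!r} not in pedigree")
        total += c(iid)
    return total / len(population)


def contribution_ratio(ancestor: str, cases: Iterable[str],
                       controls: Iterable[str], pedigree) -> ContributionReport:
    """Case/control contribution ratio for one ancestor.

    The ratio is undefined (None, flagged) when the control contribution
    is zero.
    """
    ped = _as_pedigree(pedigree)
    cc = genetic_contribution(ancestor, cases, ped)
    cn = genetic_contribution(ancestor, controls, ped)
    if cn == 0.0:
        logger.warning("ancestor %s contributes 0 to controls; ratio undefined",
                       ancestor)
        return ContributionReport(ancestor, cc, cn, None)
    return ContributionReport(ancestor, cc, cn, cc / cn)


def rank_contribution_ratios(ancestors: Iterable[str], cases: Iterable[str],
                             controls: Iterable[str], pedigree,
                             floor: float = 0.01) -> pd.DataFrame:
    """Contribution ratios for ancestors above a reporting floor.

    Ancestors whose contribution to either population is below ``floor``
    (default 1%) are excluded from the ranking; the mean and SD of the
    ratio over the qualifying ancestors are attached as frame attrs
    (report statistics only, no thresholding of the computation).
    """
    ped = _as_pedigree(pedigree)
    cases = list(cases)
    controls = list(controls)
    rows = []
    for anc in ancestors:
        rep = contribution_ratio(anc, cases, controls, ped)
        if rep.contrib_cases >= floor and rep.contrib_controls >= floor:
            rows.append(rep)
    df = pd.DataFrame({
        "ancestor": [r.ancestor for r in rows],
        "contrib_cases": [r.contrib_cases for r in rows],
        "contrib_controls": [r.contrib_controls for r in rows],
        "ratio": [r.ratio for r in rows],
    }).sort_values("ratio", ascending=False, na_position="last").reset_index(drop=True)
    if len(df):
        df.attrs["ratio_mean"] = float(df["ratio"].mean())
        df.attrs["ratio_sd"] = float(df["ratio"].std(ddof=1)) if len(df) > 1 else 0.0
    return df


def gene_dropping_contribution(ancestor: str, population: Iterable[str],
                               pedigree, n_drops: int, seed: int = 0) -> float:
    """Monte-Carlo gene dropping estimate of the genetic contribution.

    Drops two distinguishable alleles from the ancestor through the
    pedigree (each individual transmits one of its two alleles at random)
    and measures the fraction of population allele slots descending from
    the ancestor.  Serves as an independent cross-check of the exact
    recursion on small pedigrees.
    """
    import numpy as np

    ped = _as_pedigree(pedigree)
    population = list(population)
    order = _topological_order(ped)
    rng = np.random.default_rng(seed)
    index = {iid: k for k, iid in enumerate(order)}
    # carry[k, r, slot]: does replicate r's allele in slot of individual k
    # descend from the ancestor?  Vectorised over replicates.
    carry = np.zeros((len(order), n_drops, 2), dtype=bool)
    for iid in order:
        k = index[iid]
        if iid == ancestor:
            carry[k] = True
            continue
        for slot, parent in zip((0, 1), ped.parents[iid]):
            if parent is None or parent not in index:
                continue
            pick = rng.integers(0, 2, size=n_drops)
            carry[k, :, slot] = carry[index[parent], np.arange(n_drops), pick]
    rows = [index[i] for i in population]
    return float(carry[rows].mean())


def _topological_order(ped: Pedigree) -> list[str]:
    order: list[str] = []
    seen: set[str] = set()
    for start in ped.parents:
        stack = [start]
        path = []
        while stack:
            node = stack[-1]
            if node in seen:
                stack.pop()
                continue
            pending = [p for p in ped._known_parents(node)
                       if p in ped.parents and p not in seen]
            if pending:
                stack.extend(pending)
            else:
                seen.add(node)
                order.append(node)
                stack.pop()
    return order
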