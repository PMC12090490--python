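"""Forward-in-time synthetic population generator.

Emulates the data structure of a closed AI-bred beef cattle population in
which a fully penetrant recessive lethal haplotype segregates at low
frequency: discrete generations, a small sire panel used heavily each
generation, gene dropping with Poisson recombination on a 50K-like marker
grid, perinatal lethality of risk-allele homozygotes, and a small additive
heterozygote effect on a polygenic quantitative trait.

The risk allele is seeded on a single founder chromosome so that all
carriers share one ancestral flanking haplotype (the identical-by-descent
segment that homozygosity mapping exploits).  The carrier founder is
treated as a heavily used AI sire in the first generation, which starts the
allele near its target frequency; thereafter the allele drifts, and the
whole population is resampled (seed incremented, logged) when the realised
frequency misses the target by more than ``freq_tolerance`` or fewer than
``min_cases`` affected homozygotes are born.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hmap import PhasedGenotypeMatrix

logger = logging.getLogger(__name__)

#: Juvenile mortality periods, in days of age, in chronological order.
PERIODS = ("0-2", "3-14", "15-55", "56-365")
SURVIVED = "survived"

__all__ = [
    "PERIODS",
    "SURVIVED",
    "ConfigError",
    "SimulationError",
    "SimulationConfig",
    "SimulatedPopulation",
    "simulate_population",
    "simulate_matings",
    "expand_mating_counts",
    "simulate_variant_table",
    "verify_mendelian",
]


class ConfigError(ValueError):
    """Raised for an impossible or inconsistent simulation configuration."""


class SimulationError(RuntimeError):
    """Raised when a simulation cannot satisfy its resampling criteria."""


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters governing the synthetic population.

    Defaults describe a closed beef breed under AI: 1000 founders, four
    discrete generations with 25 sires each (effective size ~95, within the
    12-150 range typical of cattle breeds), ~5,000 individuals in total,
    2,000 markers on four 20-Mb chromosomes (~40 kb spacing, so a 20-marker
    sliding window spans ~0.8-1 Mb as on a 50K bovine array), a recessive
    allele targeted at frequency 2.6% with complete perinatal (0-2 d)
    lethality of homozygotes, and a heterozygote effect of -1.0 trait
    points on a trait with genetic variance 22.75 (genetic SD 4.77) and
    heritability ~0.3.  The grid is slightly denser than a real 50K array
    relative to the map length so that the identical-by-descent core shared
    by an ascertained case series (a few meioses deep) remains wider than
    one window.
    """

    n_founders: int = 1000
    n_generations: int = 4
    offspring_per_mating: int = 2
    n_markers: int = 2000
    n_chromosomes: int = 4
    chromosome_length_bp: int = 20_000_000
    risk_allele_freq: float = 0.026
    risk_locus_chrom: int = 1
    risk_locus_pos: int = 10_000_000
    lethality_penetrance_by_period: dict = field(
        default_factory=lambda: {"0-2": 1.0})
    het_trait_effect: float = -1.0
    polygenic_variance: float = 22.75
    residual_variance: float = 53.1
    recomb_rate_per_bp: float = 1e-8        # Morgans/bp, i.e. 1 cM/Mb
    marker_maf_floor: float = 0.01
    n_sires_per_generation: int = 25
    n_ascertained_cases: int = 0
    seed: int = 0
    freq_tolerance: float = 0.25
    min_cases: int = 0
    max_resamples: int = 50

    def validate(self) -> None:
        for name in ("n_founders", "n_generations", "offspring_per_mating",
                     "n_markers", "n_chromosomes", "chromosome_length_bp",
                     "n_sires_per_generation"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not 0.0 <= self.risk_allele_freq <= 1.0:
            raise ConfigError("risk_allele_freq must lie in [0,1]")
        if not 1 <= self.risk_locus_pos <= self.chromosome_length_bp:
            raise ConfigError("risk_locus_pos outside chromosome")
        if not 1 <= self.risk_locus_chrom <= self.n_chromosomes:
            raise ConfigError("risk_locus_chrom outside chromosome range")
        for period, pen in self.lethality_penetrance_by_period.items():
            if period not in PERIODS:
                raise ConfigError(f"unknown period label {period!r}")
            if not 0.0 <= pen <= 1.0:
                raise ConfigError("penetrance probabilities must lie in [0,1]")
        if self.polygenic_variance < 0 or self.residual_variance < 0:
            raise ConfigError("variances must be non-negative")
        if self.recomb_rate_per_bp < 0:
            raise ConfigError("recomb_rate_per_bp must be non-negative")
        if not 0.0 <= self.marker_maf_floor < 0.5:
            raise ConfigError("marker_maf_floor must lie in [0, 0.5)")
        if self.risk_allele_freq == 0.0 and (self.min_cases > 0
                                             or self.n_ascertained_cases > 0):
            raise ConfigError("carrier matings / affected cases are impossible "
                              "with risk_allele_freq = 0")


@dataclass
class SimulatedPopulation:
    """Output of :func:`simulate_population`.

    ``pedigree`` has columns id, sire, dam, sex, birth_year (the generation
    number; "0" marks an unknown parent).  ``genotypes`` carries the marker
    haplotypes only; the causal risk locus is untyped, its per-individual
    dosage is in ``risk_genotypes``.  ``trait_values`` holds NaN for
    individuals that died before recording.
    """

    pedigree: pd.DataFrame
    genotypes: PhasedGenotypeMatrix
    risk_genotypes: dict
    survival: dict
    trait_values: dict
    risk_haplotypes: np.ndarray = field(repr=False, default=None)
    config: SimulationConfig = None
    realised_freq: float = float("nan")
    attempts: int = 1
    ascertained_ids: list = field(default_factory=list)

    @property
    def case_ids(self) -> list[str]:
        return [i for i, d in self.risk_genotypes.items() if d == 2]

    def survivor_ids(self) -> list[str]:
        return [i for i, s in self.survival.items() if s == SURVIVED]


def _marker_map(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Uniform grid plus jitter; 1-based, strictly increasing positions."""
    per = np.full(cfg.n_chromosomes, cfg.n_markers // cfg.n_chromosomes)
    per[: cfg.n_markers % cfg.n_chromosomes] += 1
    rows = []
    for chrom in range(1, cfg.n_chromosomes + 1):
        n = int(per[chrom - 1])
        spacing = cfg.chromosome_length_bp / n
        base = (np.arange(n) + 0.5) * spacing
        jitter = rng.uniform(-0.3 * spacing, 0.3 * spacing, size=n)
        pos = np.clip(np.round(base + jitter), 1, cfg.chromosome_length_bp)
        pos = np.sort(pos.astype(np.int64))
        for i in range(1, n):
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1
        rows.append(pd.DataFrame({
            "chrom": chrom,
            "pos": pos,
            "marker_id": [f"M{chrom}_{i + 1}" for i in range(n)],
        }))
    return pd.concat(rows, ignore_index=True)


def _meiosis(parent_haps: np.ndarray, chrom_slices, chrom_len: int,
             rate: float, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a (2, M) parental pair by Poisson recombination.

    Crossover count per chromosome ~ Poisson(rate * length), positions
    uniform; the transmitted haplotype alternates at crossovers, starting
    from a random strand.
    """
    gamete = np.empty(parent_haps.shape[1], dtype=np.uint8)
    lam = rate * chrom_len
    for (i0, i1), pos in chrom_slices:
        start = int(rng.integers(0, 2))
        n_x = int(rng.poisson(lam))
        if n_x == 0:
            gamete[i0:i1] = parent_haps[start, i0:i1]
            continue
        xpos = np.sort(rng.uniform(0.0, chrom_len, size=n_x))
        phase = (start + np.searchsorted(xpos, pos)) % 2
        gamete[i0:i1] = parent_haps[phase, np.arange(i0, i1)]
    return gamete


def _death_period(dosage: int, penetrance: dict, rng: np.random.Generator) -> str:
    """Period of death for a homozygote (others always survive here).

    Baseline (genotype-independent) calf mortality is modelled in
    :func:`simulate_matings`, not in the population simulator, where it
    would only thin the pedigree without changing any analysed contrast.
    """
    if dosage < 2:
        return SURVIVED
    for period in PERIODS:
        if rng.random() < penetrance.get(period, 0.0):
            return period
    return SURVIVED


def _simulate_once(cfg: SimulationConfig, seed: int):
    rng = np.random.default_rng(seed)
    markers = _marker_map(cfg, rng)

    # Carry the untyped risk locus as one extra column inserted at its map
    # position so recombination treats it like any other site.
    chrom_arr = markers["chrom"].to_numpy()
    pos_arr = markers["pos"].to_numpy(dtype=float)
    on_chrom = np.flatnonzero(chrom_arr == cfg.risk_locus_chrom)
    risk_col = int(on_chrom[0] + np.searchsorted(pos_arr[on_chrom],
                                                 cfg.risk_locus_pos))
    all_chrom = np.insert(chrom_arr, risk_col, cfg.risk_locus_chrom)
    all_pos = np.insert(pos_arr, risk_col, float(cfg.risk_locus_pos))
    M = len(all_pos)
    marker_cols = np.delete(np.arange(M), risk_col)

    chrom_slices = []
    for chrom in range(1, cfg.n_chromosomes + 1):
        idx = np.flatnonzero(all_chrom == chrom)
        chrom_slices.append(((int(idx[0]), int(idx[-1]) + 1), all_pos[idx]))

    # Founders: Hardy-Weinberg draws at per-marker frequencies whose MAF
    # respects the floor; sexes alternate so both are always present.
    nF = cfg.n_founders
    p = rng.uniform(cfg.marker_maf_floor, 1.0 - cfg.marker_maf_floor,
                    size=len(markers))
    founder_H = np.zeros((nF, 2, M), dtype=np.uint8)
    founder_H[:, :, marker_cols] = (
        rng.random((nF, 2, len(markers))) < p).astype(np.uint8)
    carrier_row = None
    if cfg.risk_allele_freq > 0:
        carrier_row = 0                       # male founder, the future AI bull
        founder_H[carrier_row, 0, risk_col] = 1

    haps: list[np.ndarray] = [founder_H[i] for i in range(nF)]
    ids = [f"G0_{i + 1:05d}" for i in range(nF)]
    sire_l = ["0"] * nF
    dam_l = ["0"] * nF
    sex_l = ["M" if i % 2 == 0 else "F" for i in range(nF)]
    gen_l = [0] * nF
    a_va = cfg.polygenic_variance
    polygenic = list(rng.normal(0.0, np.sqrt(a_va), size=nF))
    survival: list[str] = [
        _death_period(int(founder_H[i, :, risk_col].sum()),
                      cfg.lethality_penetrance_by_period, rng)
        for i in range(nF)
    ]

    prev = list(range(nF))
    for g in range(1, cfg.n_generations + 1):
        alive = [i for i in prev if survival[i] == SURVIVED]
        males = [i for i in alive if sex_l[i] == "M"]
        females = [i for i in alive if sex_l[i] == "F"]
        if not males or not females:
            raise SimulationError(f"generation {g}: no surviving "
                                  f"{'males' if not males else 'females'}")
        n_s = min(cfg.n_sires_per_generation, len(males))
        panel = rng.choice(males, size=n_s, replace=False)
        dams = np.array(females)
        sires = rng.choice(panel, size=len(dams))
        if g == 1 and carrier_row is not None and survival[carrier_row] == SURVIVED:
            # AI-style heavy use of the carrier founder: share 4*fA of
            # matings puts the expected allele frequency at the target.
            n_c = min(len(dams), int(round(4 * cfg.risk_allele_freq * len(dams))))
            if n_c > 0:
                sires[rng.choice(len(dams), size=n_c, replace=False)] = carrier_row
        new = []
        for d_i, s_i in zip(dams, sires):
            for _ in range(cfg.offspring_per_mating):
                pat = _meiosis(haps[s_i], chrom_slices,
                               cfg.chromosome_length_bp, cfg.recomb_rate_per_bp, rng)
                mat = _meiosis(haps[d_i], chrom_slices,
                               cfg.chromosome_length_bp, cfg.recomb_rate_per_bp, rng)
                row = len(ids)
                haps.append(np.stack([pat, mat]))
                ids.append(f"G{g}_{len(new) + 1:05d}")
                sire_l.append(ids[s_i])
                dam_l.append(ids[d_i])
                sex_l.append("M" if rng.random() < 0.5 else "F")
                gen_l.append(g)
                polygenic.append(0.5 * (polygenic[s_i] + polygenic[d_i])
                                 + rng.normal(0.0, np.sqrt(a_va / 2.0)))
                dos = int(haps[row][:, risk_col].sum())
                survival.append(_death_period(
                    dos, cfg.lethality_penetrance_by_period, rng))
                new.append(row)
        prev = new

    # Ascertained case series: affected offspring of carrier x carrier
    # matings between surviving population members.  The case count is a
    # property of the study design (a case series is collected against a
    # much larger birth cohort than is simulated), so it is configured
    # directly rather than scaled with the cohort.
    ascertained: list[str] = []
    n_main = len(ids)
    if cfg.n_ascertained_cases > 0:
        # At-risk matings cluster on recent descendants of the carrier
        # origin (the recent inbreeding loops that make homozygosity
        # mapping work), so case parents are drawn from the earliest
        # generations of surviving heterozygotes: their flanking
        # identical-by-descent segments are then few meioses old and long.
        def het_of(sex: str, max_gen: int) -> list[int]:
            return [i for i in range(n_main)
                    if survival[i] == SURVIVED and sex_l[i] == sex
                    and gen_l[i] <= max_gen
                    and int(haps[i][:, risk_col].sum()) == 1]

        het_m: list[int] = []
        het_f: list[int] = []
        for max_gen in range(1, cfg.n_generations + 1):
            het_m, het_f = het_of("M", max_gen), het_of("F", max_gen)
            if len(het_m) >= 8 and len(het_f) >= 8:
                break
        if not het_m or not het_f:
            raise SimulationError("no surviving heterozygous parents available "
                                  "for the ascertained case series")
        # Distinct dams where possible (cases come from different herds);
        # sires may repeat (AI bulls serve many herds).
        dam_pool = list(rng.permutation(het_f))
        for k in range(cfg.n_ascertained_cases):
            s_i = int(rng.choice(het_m))
            d_i = int(dam_pool[k % len(dam_pool)])
            for _ in range(256):
                pat = _meiosis(haps[s_i], chrom_slices,
                               cfg.chromosome_length_bp, cfg.recomb_rate_per_bp,
                               rng)
                if pat[risk_col]:
                    break
            else:  # pragma: no cover - p = (1/2)^256
                raise SimulationError("carrier gamete rejection did not converge")
            for _ in range(256):
                mat = _meiosis(haps[d_i], chrom_slices,
                               cfg.chromosome_length_bp, cfg.recomb_rate_per_bp,
                               rng)
                if mat[risk_col]:
                    break
            else:  # pragma: no cover
                raise SimulationError("carrier gamete rejection did not converge")
            iid = f"CASE_{k + 1:03d}"
            haps.append(np.stack([pat, mat]))
            ids.append(iid)
            sire_l.append(ids[s_i])
            dam_l.append(ids[d_i])
            sex_l.append("M" if rng.random() < 0.5 else "F")
            gen_l.append(max(gen_l[s_i], gen_l[d_i]) + 1)
            polygenic.append(0.5 * (polygenic[s_i] + polygenic[d_i])
                             + rng.normal(0.0, np.sqrt(a_va / 2.0)))
            survival.append(_death_period(2, cfg.lethality_penetrance_by_period,
                                          rng))
            ascertained.append(iid)

    H = np.stack(haps)
    dosages = H[:, :, risk_col].sum(axis=1).astype(int)
    final = [i for i in range(n_main) if gen_l[i] == cfg.n_generations]
    realised = float(H[final][:, :, risk_col].mean()) if final else 0.0
    n_cases = int((dosages == 2).sum())

    residual = rng.normal(0.0, np.sqrt(cfg.residual_variance), size=len(ids))
    traits = {}
    for i, iid in enumerate(ids):
        if survival[i] == SURVIVED:
            traits[iid] = (min(dosages[i], 1) * cfg.het_trait_effect
                           + polygenic[i] + residual[i])
        else:
            traits[iid] = float("nan")

    pedigree = pd.DataFrame({
        "id": ids, "sire": sire_l, "dam": dam_l,
        "sex": sex_l, "birth_year": gen_l,
    })
    gmat = PhasedGenotypeMatrix(ids, markers, H[:, :, marker_cols])
    pop = SimulatedPopulation(
        pedigree=pedigree,
        genotypes=gmat,
        risk_genotypes={iid: int(d) for iid, d in zip(ids, dosages)},
        survival=dict(zip(ids, survival)),
        trait_values=traits,
        risk_haplotypes=H[:, :, risk_col].copy(),
        config=cfg,
        realised_freq=realised,
        ascertained_ids=ascertained,
    )
    return pop, realised, n_cases


def simulate_population(config: SimulationConfig) -> SimulatedPopulation:
    """Simulate a pedigree, phased genotypes, survival and trait values.

    Fully reproducible from ``config.seed``.  Resamples with an
    incremented seed (logged) when the realised final-generation risk
    allele frequency deviates from the target by more than
    ``freq_tolerance`` (relative), or fewer than ``min_cases`` homozygotes
    were born; raises :class:`SimulationError` after ``max_resamples``.
    """
    config.validate()
    target = config.risk_allele_freq
    for attempt in range(config.max_resamples + 1):
        seed = config.seed + attempt
        try:
            pop, realised, n_cases = _simulate_once(config, seed)
        except SimulationError as exc:
            logger.info("attempt %d (seed %d) failed (%s); resampling",
                        attempt + 1, seed, exc)
            continue
        ok = True
        if target > 0 and abs(realised - target) / target > config.freq_tolerance:
            ok = False
            logger.info("attempt %d (seed %d): realised fA %.4f misses target "
                        "%.4f; resampling", attempt + 1, seed, realised, target)
        if n_cases < config.min_cases:
            ok = False
            logger.info("attempt %d (seed %d): %d affected homozygotes < "
                        "min_cases %d; resampling", attempt + 1, seed,
                        n_cases, config.min_cases)
        if ok:
            pop.attempts = attempt + 1
            return pop
    raise SimulationError(
        f"no simulation satisfied the resampling criteria in "
        f"{config.max_resamples + 1} attempts (target fA={target}, "
        f"min_cases={config.min_cases})")


def verify_mendelian(pop: SimulatedPopulation) -> bool:
    """Allele-path check of gene-dropping consistency.

    Every non-founder's paternal (maternal) haplotype must be a mosaic of
    the sire's (dam's) two haplotypes: at each site the transmitted allele
    equals one of the parent's two alleles.  Checks marker columns and the
    risk locus.
    """
    idx = {iid: i for i, iid in enumerate(pop.genotypes.individuals)}
    H = pop.genotypes.haplotypes
    R = pop.risk_haplotypes
    for row in pop.pedigree.itertuples(index=False):
        if row.sire == "0" and row.dam == "0":
            continue
        i = idx[row.id]
        for hap_no, parent in ((0, row.sire), (1, row.dam)):
            if parent == "0":
                continue
            pidx = idx[parent]
            child = H[i, hap_no]
            ok = ((child == H[pidx, 0]) | (child == H[pidx, 1])).all()
            ok = ok and (R[i, hap_no] == R[pidx]).any()
            if not ok:
                return False
    return True


# ---------------------------------------------------------------------------
# Mating-type mortality simulator
# ---------------------------------------------------------------------------

MATING_TYPES = ("1x1", "1x0", "0x1", "0x0")


def simulate_matings(fA: float, penetrance: float, mu_baseline: float,
                     n_matings: int, seed: int) -> pd.DataFrame:
    """Monte-Carlo mating-type mortality counts.

    For each mating type sire x maternal-grandsire (``n_matings`` calves
    each), the dam's paternal allele comes from the grandsire's genotype and
    her maternal allele from the population at frequency ``fA``; dams
    homozygous for the risk allele are excluded with probability
    ``penetrance`` (they would have died as calves) and redrawn.  Offspring
    genotypes follow Mendelian segregation; homozygotes die with probability
    ``mu_baseline + penetrance * (1 - mu_baseline)``, all others with the
    baseline ``mu_baseline``.

    Returns a table with one row per mating type: columns ``mating_type``,
    ``n``, ``deaths``.
    """
    for name, v in (("fA", fA), ("penetrance", penetrance),
                    ("mu_baseline", mu_baseline)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0,1]")
    if n_matings < 0:
        raise ValueError("n_matings must be >= 0")
    if n_matings == 0:
        return pd.DataFrame(columns=["mating_type", "n", "deaths"])
    rng = np.random.default_rng(seed)
    rows = []
    for mt in MATING_TYPES:
        sire_d, mgs_d = int(mt[0]), int(mt[2])
        dam_pat = rng.random(n_matings) < (mgs_d / 2.0)
        dam_mat = rng.random(n_matings) < fA
        # Exclude dams that were homozygous and died young; redraw them.
        for _ in range(64):
            hom_dam = dam_pat & dam_mat
            dead_dam = hom_dam & (rng.random(n_matings) < penetrance)
            if not dead_dam.any():
                break
            k = int(dead_dam.sum())
            dam_pat[dead_dam] = rng.random(k) < (mgs_d / 2.0)
            dam_mat[dead_dam] = rng.random(k) < fA
        dam_dosage = dam_pat.astype(int) + dam_mat.astype(int)
        from_sire = rng.random(n_matings) < (sire_d / 2.0)
        from_dam = rng.random(n_matings) < (dam_dosage / 2.0)
        hom = from_sire & from_dam
        p_death = np.where(hom, mu_baseline + penetrance * (1.0 - mu_baseline),
                           mu_baseline)
        deaths = int((rng.random(n_matings) < p_death).sum())
        rows.append({"mating_type": mt, "n": n_matings, "deaths": deaths})
    return pd.DataFrame(rows)


def expand_mating_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Calf-level 0/1 death indicators from aggregated mating-type counts."""
    frames = []
    for row in counts.itertuples(index=False):
        died = np.zeros(int(row.n), dtype=int)
        died[: int(row.deaths)] = 1
        frames.append(pd.DataFrame({"mating_type": row.mating_type, "died": died}))
    if not frames:
        return pd.DataFrame(columns=["mating_type", "died"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Sequenced-case variant table emulator
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_variant_table(interval: tuple, case_ids,
                           n_in_interval_hom: int = 3115,
                           n_pass_breed: int = 7,
                           n_pass_all: int = 1,
                           n_not_hom: int = 40,
                           n_outside: int = 160,
                           seed: int = 0) -> tuple[pd.DataFrame, tuple]:
    """Variant table for sequenced cases with control-panel presence flags.

    Emulates the structure of a candidate list from two sequenced affected
    calves: ``n_in_interval_hom`` variants inside the mapping interval that
    both cases carry homozygously, of which ``n_pass_breed`` are absent from
    the within-breed control panel and ``n_pass_all`` are additionally
    absent from the multi-breed panel (the causal candidates).  Decoy rows
    inside the interval without case homozygosity (``n_not_hom``, including
    some with a missing genotype) and rows outside the interval
    (``n_outside``) exercise the earlier filter stages.  Rows are shuffled.

    Returns the table and the (chrom, pos, ref, alt) key of the planted
    causal variant (the first of the ``n_pass_all`` survivors).
    """
    if not (0 <= n_pass_all <= n_pass_breed <= n_in_interval_hom):
        raise ValueError("need n_pass_all <= n_pass_breed <= n_in_interval_hom")
    chrom, start, end = interval
    case_ids = list(case_ids)
    rng = np.random.default_rng(seed)
    n_inside = n_in_interval_hom + n_not_hom
    total = n_inside + n_outside

    pos_inside = np.sort(rng.choice(np.arange(start, end + 1),
                                    size=n_inside, replace=False))
    span = end - start + 1
    pos_outside = np.sort(rng.choice(
        np.concatenate([np.arange(max(1, start - span), start),
                        np.arange(end + 1, end + span)]),
        size=n_outside, replace=False))
    ref = rng.choice(_BASES, size=total)
    alt = np.array([rng.choice([b for b in _BASES if b != r]) for r in ref])
    vtype = rng.choice(["SNP", "InDel", "SV"], size=total, p=[0.88, 0.10, 0.02])

    df = pd.DataFrame({
        "chrom": chrom,
        "pos": np.concatenate([pos_inside, pos_outside]),
        "ref": ref, "alt": alt, "type": vtype,
    })
    for cid in case_ids:
        df[f"genotype_{cid}"] = "hom_alt"
    # Decoys inside the interval: not homozygous in every case.
    bad = rng.choice(["het", "hom_ref", "missing"], size=n_not_hom)
    which_case = rng.integers(0, len(case_ids), size=n_not_hom)
    for j in range(n_not_hom):
        df.loc[n_in_interval_hom + j,
               f"genotype_{case_ids[which_case[j]]}"] = bad[j]

    breed = np.ones(total, dtype=bool)
    other = np.ones(total, dtype=bool)
    keep = rng.choice(n_in_interval_hom, size=n_pass_breed, replace=False)
    breed[keep] = False
    causal_rows = keep[:n_pass_all]
    other[causal_rows] = False
    # Outside/non-hom rows: random flags (they fall at earlier stages anyway).
    tail = np.arange(n_in_interval_hom, total)
    breed[tail] = rng.random(len(tail)) < 0.95
    other[tail] = rng.random(len(tail)) < 0.95
    df["present_in_breed_controls"] = breed
    df["present_in_other_breeds"] = other

    causal = df.loc[causal_rows[0]] if n_pass_all else None
    causal_key = (None if causal is None else
                  (causal["chrom"], int(causal["pos"]), causal["ref"], causal["alt"]))
    df = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    return df, causal_key
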