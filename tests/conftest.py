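import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from recmap.hmap import PhasedGenotypeMatrix
from recmap.simulate import SimulationConfig, simulate_population

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def toy_pedigree() -> pd.DataFrame:
    """Twelve individuals with an inbreeding loop through founder S1."""
    rows = [
        ("S1", "0", "0"), ("D1", "0", "0"), ("S2", "0", "0"), ("D2", "0", "0"),
        ("A", "S1", "D1"), ("B", "S1", "D2"), ("C", "S2", "D2"),
        ("E", "A", "B"),                      # loop: A and B share S1
        ("F", "A", "C"),
        ("G", "E", "C"),
        ("H", "F", "G"),
        ("X", "H", "G"),                      # second loop through G
    ]
    return pd.DataFrame(rows, columns=["id", "sire", "dam"])


@pytest.fixture(scope="session")
def small_pop():
    """A quick population for unit tests (about a second to build)."""
    cfg = SimulationConfig(
        n_founders=200, n_generations=3, offspring_per_mating=2,
        n_markers=400, n_chromosomes=2, chromosome_length_bp=8_000_000,
        risk_locus_chrom=1, risk_locus_pos=4_000_000,
        risk_allele_freq=0.05, n_ascertained_cases=6, seed=11,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def mapped_pop():
    """Study-scale population used by the mapping and carrier-status tests."""
    cfg = SimulationConfig(risk_allele_freq=0.03, n_ascertained_cases=8,
                           seed=2000)
    return simulate_population(cfg)


def make_matrix(haps: np.ndarray, positions=None, chrom=1) -> PhasedGenotypeMatrix:
    """Helper: wrap an (n, 2, m) allele array into a genotype matrix."""
    haps = np.asarray(haps, dtype=np.uint8)
    m = haps.shape[2]
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    markers = pd.DataFrame({
        "chrom": chrom, "pos": positions,
        "marker_id": [f"M{j}" for j in range(m)],
    })
    inds = [f"I{i}" for i in range(haps.shape[0])]
    return PhasedGenotypeMatrix(inds, markers, haps)
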