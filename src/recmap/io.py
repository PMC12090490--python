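"""Readers and writers for the plain-text formats the pipeline consumes.

Pedigrees travel as CSV (id,sire,dam,sex,birth_year; 0 = unknown parent),
phased genotypes as PLINK-style PED/MAP text (two allele columns per
marker, first = paternal haplotype) or phased VCF (``|`` separator
required, no missing genotypes), and phenotypes / matings / variant flags
as TSV.  All coordinates are 1-based.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .hmap import PhasedGenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_pedigree_csv", "write_pedigree_csv",
    "read_ped_map", "write_ped_map",
    "read_phased_vcf", "write_phased_vcf",
    "read_id_list", "read_tsv", "write_tsv",
]

_SEX_OUT = {"M": "1", "F": "2", "unknown": "0"}
_SEX_IN = {"1": "M", "2": "F"}


def read_pedigree_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    for col in ("id", "sire", "dam"):
        if col not in df.columns:
            raise ValueError(f"pedigree CSV lacks column {col!r}")
    return df


def write_pedigree_csv(pedigree: pd.DataFrame, path) -> None:
    pedigree.to_csv(path, index=False)


def write_ped_map(gmat: PhasedGenotypeMatrix, prefix) -> None:
    """PLINK-style text PED/MAP carrying phase in the allele column order."""
    prefix = Path(prefix)
    m = gmat.markers
    with open(prefix.with_suffix(".map"), "w") as fh:
        for row in m.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.marker_id}\t0\t{row.pos}\n")
    H = gmat.haplotypes + 1          # alleles coded 1/2
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, iid in enumerate(gmat.individuals):
            pairs = np.empty(2 * gmat.n_markers, dtype=np.uint8)
            pairs[0::2] = H[i, 0]
            pairs[1::2] = H[i, 1]
            fh.write(f"0 {iid} 0 0 0 -9 " + " ".join(map(str, pairs)) + "\n")


def read_ped_map(prefix) -> PhasedGenotypeMatrix:
    prefix = Path(prefix)
    m = pd.read_csv(prefix.with_suffix(".map"), sep=r"\s+", header=None,
                    names=["chrom", "marker_id", "cm", "pos"])
    markers = m[["chrom", "pos", "marker_id"]]
    individuals, rows = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            fields = line.split()
            if len(fields) != 6 + 2 * len(m):
                raise ValueError("PED row length does not match MAP")
            individuals.append(fields[1])
            alleles = np.array(fields[6:], dtype=np.int16)
            if not set(np.unique(alleles)) <= {1, 2}:
                raise ValueError("PED alleles must be coded 1/2 (no missing)")
            rows.append(np.stack([alleles[0::2], alleles[1::2]]) - 1)
    return PhasedGenotypeMatrix(individuals, markers,
                                np.stack(rows).astype(np.uint8))


def write_phased_vcf(gmat: PhasedGenotypeMatrix, path) -> None:
    """Minimal phased VCF (GT only, ``|`` separated, REF=A ALT=G)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(gmat.markers["chrom"]):
            sub = gmat.markers[gmat.markers["chrom"] == chrom]
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gmat.individuals) + "\n")
        H = gmat.haplotypes
        for j, row in enumerate(gmat.markers.itertuples(index=False)):
            gts = "\t".join(f"{H[i, 0, j]}|{H[i, 1, j]}"
                            for i in range(gmat.n_individuals))
            fh.write(f"{row.chrom}\t{row.pos}\t{row.marker_id}\tA\tG\t.\t.\t.\tGT\t"
                     + gts + "\n")


def read_phased_vcf(path) -> PhasedGenotypeMatrix:
    """Read a phased biallelic VCF; rejects unphased or missing genotypes."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    chroms, poss, ids, haps = [], [], [], []
    for var in vcf:
        g = np.array(var.genotypes)          # (n, 3): allele, allele, phased
        if (g[:, :2] < 0).any():
            raise ValueError(f"missing genotype at {var.CHROM}:{var.POS}; "
                             "the pipeline requires imputed data")
        if not g[:, 2].all():
            raise ValueError(f"unphased genotype at {var.CHROM}:{var.POS}")
        if g[:, :2].max() > 1:
            raise ValueError(f"non-biallelic genotype at {var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        haps.append(g[:, :2].T)              # (2, n)
    markers = pd.DataFrame({"chrom": chroms, "pos": poss, "marker_id": ids})
    H = np.stack(haps, axis=-1)              # (2, n, M)
    return PhasedGenotypeMatrix(individuals, markers,
                                np.swapaxes(H, 0, 1).astype(np.uint8))


def read_id_list(path) -> list[str]:
    """One identifier per line; blank lines and #-comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split()[0])
    return out


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
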