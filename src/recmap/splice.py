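"""In-silico interpretation of aberrant splicing outcomes.

Deep intronic variants can activate latent splice sites, so that a cryptic
exon (or part of the surrounding intron) is included between two reference
exons.  Given a gene model and an inserted segment at an exon junction,
this module assembles the mutant isoform, translates it, locates a
premature termination codon (PTC), applies the canonical 50-nt rule for
nonsense-mediated decay (NMD: the PTC must lie at least 50 nt upstream of
the final exon-exon junction), and measures the fraction of the reference
protein lost.  A generic additive position-weight-matrix scanner covers
exonic-splicing-enhancer motif scoring; matrices are user configuration,
not shipped as authoritative data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "Exon",
    "GeneModel",
    "IsoformConsequence",
    "build_isoform",
    "orf_consequence",
    "ese_scan",
    "ese_allelic_delta",
]

_VALID = set("ACGT")


@dataclass(frozen=True)
class Exon:
    """One exon: 1-based inclusive genomic coordinates plus its sequence.

    Inserted (cryptic) segments may carry ``start = end = 0`` when their
    genomic coordinates are not modelled.
    """

    start: int
    end: int
    seq: str

    def __post_init__(self):
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        if set(seq) - _VALID:
            raise ValueError("exon sequence contains non-ACGT characters")
        if self.start and self.end and len(seq) != self.end - self.start + 1:
            raise ValueError("exon sequence length does not match coordinates")


@dataclass(frozen=True)
class GeneModel:
    """Exons in transcription order with CDS bounds in transcript coordinates.

    ``cds_start``/``cds_end`` are 1-based inclusive positions in the
    spliced transcript; the CDS includes the stop codon.
    """

    exons: tuple
    strand: str = "+"
    cds_start: int = 1
    cds_end: int | None = None
    inserted_length: int = 0            # bp added relative to the reference
    inserted_position: int | None = None

    def __post_init__(self):
        exons = tuple(e if isinstance(e, Exon) else Exon(**e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValueError("gene model needs at least one exon")
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be '+' or '-'")
        coords = [(e.start, e.end) for e in exons if e.start and e.end]
        for (s1, e1), (s2, e2) in zip(coords, coords[1:]):
            if s2 <= e1:
                raise ValueError("exons must be non-overlapping and ordered 5'->3'")
        total = sum(len(e.seq) for e in exons)
        cds_end = self.cds_end if self.cds_end is not None else total
        object.__setattr__(self, "cds_end", cds_end)
        if not 1 <= self.cds_start <= cds_end <= total:
            raise ValueError("CDS must lie within the transcript")

    @property
    def sequence(self) -> str:
        return "".join(e.seq for e in self.exons)

    def junctions(self) -> list[int]:
        """Transcript positions of exon 3' ends, except the last exon."""
        out, acc = [], 0
        for e in self.exons[:-1]:
            acc += len(e.seq)
            out.append(acc)
        return out


def build_isoform(model: GeneModel, insertion: tuple[int, str]) -> GeneModel:
    """Splice an inserted segment into the transcript at an exon junction.

    ``insertion`` is (transcript position of the junction, sequence); the
    position must be one of ``model.junctions()``.  An empty sequence is
    the identity.  Returns the mutant isoform as a new gene model whose
    ``sequence`` is the spliced transcript and whose CDS start is shifted
    when the insertion lies upstream of it.
    """
    position, seq = insertion
    seq = seq.upper()
    if seq and set(seq) - _VALID:
        raise ValueError("insertion contains non-ACGT characters")
    if not seq:
        return model
    junctions = model.junctions()
    if position not in junctions:
        raise ValueError(f"insertion position {position} is not an exon junction "
                         f"(junctions: {junctions})")
    k = junctions.index(position)
    exons = list(model.exons)
    exons.insert(k + 1, Exon(0, 0, seq))
    cds_start = model.cds_start + (len(seq) if position < model.cds_start else 0)
    return replace(model, exons=tuple(exons), cds_start=cds_start,
                   inserted_length=len(seq), inserted_position=position)


@dataclass
class IsoformConsequence:
    """Coding outcome of a mis-spliced isoform relative to the reference."""

    inserted_segment: tuple             # (length bp, transcript position)
    frameshift: bool
    ptc_transcript_pos: int | None      # 1-based position of the stop codon
    nmd_predicted: bool
    truncation_fraction: float
    mutant_protein: str = field(repr=False, default="")
    reference_protein: str = field(repr=False, default="")


def _first_stop(cds: str) -> tuple[str, int | None]:
    """Translate codons until the first stop; return (protein, codon index)."""
    prot = []
    for i in range(0, len(cds) - 2, 3):
        aa = str(Seq(cds[i:i + 3]).translate())
        if aa == "*":
            return "".join(prot), i // 3
        prot.append(aa)
    return "".join(prot), None


def orf_consequence(model: GeneModel, isoform: GeneModel,
                    nmd_rule_nt: int = 50) -> IsoformConsequence:
    """Translate a (possibly mis-spliced) isoform and classify the outcome.

    The reference CDS must begin with ATG and translate without an internal
    stop.  The isoform is read from its (shifted) start codon; the first
    stop is premature when it yields a protein shorter than the reference.
    NMD is predicted when the PTC starts at least ``nmd_rule_nt``
    nucleotides upstream of the isoform's final exon-exon junction.
    """
    ref_tx = model.sequence
    ref_cds = ref_tx[model.cds_start - 1:model.cds_end]
    if not ref_cds.startswith("ATG"):
        raise ValueError("reference CDS lacks an ATG start codon")
    ref_prot, ref_stop = _first_stop(ref_cds)
    if ref_stop is not None and (ref_stop + 1) * 3 < len(ref_cds):
        raise ValueError("reference CDS contains an internal stop codon")
    n_ref = len(ref_prot)
    if n_ref == 0:
        raise ValueError("reference CDS encodes no amino acids")

    iso_tx = isoform.sequence
    iso_cds = iso_tx[isoform.cds_start - 1:]
    if not iso_cds.startswith("ATG"):
        raise ValueError("isoform lost its start codon")
    mut_prot, stop_codon = _first_stop(iso_cds)
    n_mut = len(mut_prot)

    ins_len = isoform.inserted_length
    frameshift = ins_len % 3 != 0
    if stop_codon is None:
        ptc_pos = None
        premature = False
        logger.warning("isoform translates past its 3' end without a stop codon")
    else:
        ptc_pos = isoform.cds_start + stop_codon * 3   # 1-based stop-codon start
        premature = n_mut < n_ref
        if not premature:
            ptc_pos = None

    nmd = False
    if premature:
        junctions = isoform.junctions()
        if junctions:
            last_junction = junctions[-1]
            nmd = (last_junction - (ptc_pos + 2)) >= nmd_rule_nt
    truncation = max(0.0, 1.0 - n_mut / n_ref)
    return IsoformConsequence(
        inserted_segment=(ins_len, isoform.inserted_position),
        frameshift=frameshift,
        ptc_transcript_pos=ptc_pos,
        nmd_predicted=nmd,
        truncation_fraction=truncation,
        mutant_protein=mut_prot,
        reference_protein=ref_prot,
    )


def _pssm_matrix(pssm) -> tuple[np.ndarray, int]:
    """Normalise a PSSM (DataFrame indexed by base, or mapping base->row)
    to a (4, width) array in ACGT order."""
    if isinstance(pssm, pd.DataFrame):
        mat = pssm
    else:
        mat = pd.DataFrame({b: list(v) for b, v in pssm.items()}).T
    mat.index = [str(i).upper() for i in mat.index]
    if set(mat.index) != _VALID:
        raise ValueError("PSSM rows must be exactly A, C, G, T")
    arr = mat.loc[list("ACGT")].to_numpy(dtype=float)
    return arr, arr.shape[1]


def ese_scan(sequence: str, pssm, threshold: float | None = None) -> pd.DataFrame:
    """Additive log-odds PSSM scores at every offset of ``sequence``.

    Returns a frame with 1-based ``pos``, the scored ``site`` and its
    ``score``; rows below ``threshold`` are dropped when one is given.  A
    sequence shorter than the motif yields an empty result.
    """
    sequence = sequence.upper()
    if set(sequence) - _VALID:
        raise ValueError("sequence contains non-ACGT characters")
    arr, width = _pssm_matrix(pssm)
    n = len(sequence) - width + 1
    if n <= 0:
        return pd.DataFrame(columns=["pos", "site", "score"])
    codes = np.frombuffer(sequence.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    idx = lut[codes]
    scores = np.zeros(n)
    for j in range(width):
        scores += arr[idx[j:j + n], j]
    out = pd.DataFrame({
        "pos": np.arange(1, n + 1),
        "site": [sequence[i:i + width] for i in range(n)],
        "score": scores,
    })
    if threshold is not None:
        out = out[out["score"] >= threshold].reset_index(drop=True)
    return out


def ese_allelic_delta(seq_ref: str, seq_alt: str, pssm) -> pd.DataFrame:
    """Per-offset score change between two allelic sequences (alt - ref).

    Antisymmetric under swapping the alleles.  Sequences must be equal
    length (substitution alleles).
    """
    if len(seq_ref) != len(seq_alt):
        raise ValueError("allelic sequences must have equal length")
    ref = ese_scan(seq_ref, pssm)
    alt = ese_scan(seq_alt, pssm)
    return pd.DataFrame({
        "pos": ref["pos"],
        "site_ref": ref["site"],
        "site_alt": alt["site"],
        "score_ref": ref["score"],
        "score_alt": alt["score"],
        "delta": alt["score"].to_numpy() - ref["score"].to_numpy(),
    })
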