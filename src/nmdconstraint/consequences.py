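"""Minimal coding-SNV consequence calling and exhaustive enumeration.

Classifies single-nucleotide substitutions in a CDS as synonymous,
missense or nonsense by codon-table comparison, and enumerates every
possible CDS SNV (three alternate alleles per base) with its consequence
and NMD region. Substitutions within the reference stop codon are
excluded throughout: stop-lost and stop-retained classes are out of scope.

The codon->amino-acid table comes from Biopython's standard table; its
vectorised application over whole transcripts is implemented here with
numpy integer coding.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from nmdconstraint.nmd_regions import RegionAnnotation
from nmdconstraint.transcripts import CdsMap, TranscriptModel, build_cds_map

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SYNONYMOUS = "synonymous"
MISSENSE = "missense"
NONSENSE = "nonsense"
CONSEQUENCES = (SYNONYMOUS, MISSENSE, NONSENSE)


def _codon_aa_table() -> np.ndarray:
    """64-entry array: codon index (base-4, ACGT) -> single-letter aa ('*' = stop)."""
    table = np.empty(64, dtype="<U1")
    for i, b1 in enumerate(BASES):
        for j, b2 in enumerate(BASES):
            for k, b3 in enumerate(BASES):
                table[16 * i + 4 * j + k] = str(Seq(b1 + b2 + b3).translate())
    return table


_AA = _codon_aa_table()


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        codes[ord(b)] = i
    out = codes[arr]
    if (out < 0).any():
        bad = seq[int(np.argmax(codes[arr] < 0))]
        raise ValueError(f"ambiguous or non-ACGT base {bad!r} in CDS sequence")
    return out.astype(np.int64)


def classify_snv(cds_sequence: str, cds_pos: int, alt_base: str) -> str:
    """Consequence of substituting ``alt_base`` at 1-based ``cds_pos``.

    Requires a CDS whose length is divisible by 3; raises on positions in
    the reference stop codon (stop-lost is not classified).
    """
    L = len(cds_sequence)
    if L % 3 != 0:
        raise ValueError(f"CDS length {L} not divisible by 3")
    if not 1 <= cds_pos <= L:
        raise ValueError(f"cds_pos {cds_pos} outside CDS of length {L}")
    alt_base = alt_base.upper()
    if alt_base not in _BASE_INDEX:
        raise ValueError(f"ambiguous alternate base {alt_base!r}")
    ref_base = cds_sequence[cds_pos - 1].upper()
    if ref_base not in _BASE_INDEX:
        raise ValueError(f"ambiguous reference base {ref_base!r} at cds_pos {cds_pos}")
    if alt_base == ref_base:
        raise ValueError("alternate allele equals the reference allele")
    c0 = (cds_pos - 1) // 3 * 3
    codon = cds_sequence[c0 : c0 + 3].upper()
    aa_ref = str(Seq(codon).translate())
    if aa_ref == "*":
        raise ValueError(f"cds_pos {cds_pos} lies in the reference stop codon")
    mut = codon[: (cds_pos - 1) % 3] + alt_base + codon[(cds_pos - 1) % 3 + 1 :]
    aa_alt = str(Seq(mut).translate())
    if aa_alt == "*":
        return NONSENSE
    return SYNONYMOUS if aa_alt == aa_ref else MISSENSE


def enumerate_possible_snvs(
    model: TranscriptModel,
    cds_sequence: str,
    annotation: RegionAnnotation | None = None,
    cds_map: CdsMap | None = None,
) -> pd.DataFrame:
    """All possible SNVs of one transcript, classified and region-labelled.

    Three records per CDS base, minus positions in reference stop codons.
    Alleles are reported on the genomic (plus) strand so records join
    genomic rate tables directly; ``cds_ref``/``cds_alt`` carry the
    coding-strand alleles.

    Columns: chrom, pos, ref, alt, transcript_id, gene_id, cds_pos,
    cds_ref, cds_alt, consequence, region.
    """
    L = len(cds_sequence)
    if L != model.cds_length:
        raise ValueError(
            f"sequence length {L} != cds_length {model.cds_length} for {model.transcript_id}"
        )
    if L % 3 != 0:
        raise ValueError(
            f"transcript {model.transcript_id}: CDS length {L} not divisible by 3; "
            "refusing to classify"
        )
    if cds_map is None:
        cds_map = build_cds_map(model)
    code = _encode(cds_sequence)
    codon_start = np.arange(L) // 3 * 3
    codon_idx = 16 * code[codon_start] + 4 * code[codon_start + 1] + code[codon_start + 2]
    aa_ref = _AA[codon_idx]
    offset_in_codon = np.arange(L) % 3
    place = 4 ** (2 - offset_in_codon)  # positional weight of this base in the codon index

    keep = aa_ref != "*"
    pos_idx = np.nonzero(keep)[0]

    frames = []
    for alt_code in range(4):
        sel = pos_idx[code[pos_idx] != alt_code]
        new_idx = codon_idx[sel] + (alt_code - code[sel]) * place[sel]
        aa_alt = _AA[new_idx]
        cons = np.where(
            aa_alt == "*", NONSENSE, np.where(aa_alt == aa_ref[sel], SYNONYMOUS, MISSENSE)
        )
        frames.append(
            pd.DataFrame(
                {
                    "cds_pos": sel + 1,
                    "cds_alt_code": alt_code,
                    "consequence": cons,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True).sort_values(
        ["cds_pos", "cds_alt_code"], kind="mergesort", ignore_index=True
    )

    base_arr = np.array(list(BASES))
    comp_arr = np.array([_COMPLEMENT[b] for b in BASES])
    cds_ref = base_arr[code[df["cds_pos"] - 1]]
    cds_alt = base_arr[df["cds_alt_code"]]
    if model.strand == "+":
        ref, alt = cds_ref, cds_alt
    else:
        ref = comp_arr[code[df["cds_pos"] - 1]]
        alt = comp_arr[df["cds_alt_code"]]

    genomic = cds_map.genomic_positions[df["cds_pos"].to_numpy() - 1]
    out = pd.DataFrame(
        {
            "chrom": model.chrom,
            "pos": genomic,
            "ref": ref,
            "alt": alt,
            "transcript_id": model.transcript_id,
            "gene_id": model.gene_id,
            "cds_pos": df["cds_pos"].to_numpy(),
            "cds_ref": cds_ref,
            "cds_alt": cds_alt,
            "consequence": df["consequence"].to_numpy(),
        }
    )
    if annotation is not None:
        out["region"] = annotation.labels[out["cds_pos"].to_numpy() - 1].astype(str)
    return out


def consequence_counts(snvs: pd.DataFrame) -> pd.Series:
    """Count enumerated SNVs per consequence class."""
    return snvs["consequence"].value_counts().reindex(CONSEQUENCES, fill_value=0)
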