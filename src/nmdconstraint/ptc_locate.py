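"""Locating the premature termination codon created by a coding variant.

Frameshift indels usually create a stop codon downstream of the edit; the
biological consequence (NMD escape or not) depends on where that new stop
lands, not where the indel sits. This module applies a variant to the
coding sequence, scans for the first in-frame stop at or downstream of the
edit, maps the stop back to reference CDS coordinates, and looks up its
NMD region on the reference annotation. Frameshifts whose new reading
frame reaches the end of the CDS without a stop are flagged as extending
into the 3' UTR and excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

from nmdconstraint.nmd_regions import RegionAnnotation

STOP_CODONS = {"TAA", "TAG", "TGA"}

SNV = "snv"
INSERTION = "insertion"
DELETION = "deletion"
DELINS = "delins"


@dataclass(frozen=True)
class VariantAllele:
    """One coding variant in CDS coordinates.

    ``cds_pos`` is the 1-based position of the first reference base in
    ``ref``. Pure insertions use the anchor-base convention: ``ref`` is
    the single base *after which* the extra sequence is inserted
    (``alt = ref + inserted``), as in VCF.
    """

    transcript_id: str
    cds_pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("empty allele; use the VCF anchor-base convention")
        for allele in (self.ref, self.alt):
            if any(b not in "ACGT" for b in allele.upper()):
                raise ValueError(f"non-ACGT allele {allele!r}")

    @property
    def net_length_change(self) -> int:
        return len(self.alt) - len(self.ref)

    @property
    def variant_class(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return SNV
        if len(self.alt) > len(self.ref) and self.alt.upper().startswith(self.ref.upper()):
            return INSERTION
        if len(self.ref) > len(self.alt) and self.ref.upper().startswith(self.alt.upper()):
            return DELETION
        return DELINS

    @property
    def is_frameshift(self) -> bool:
        return self.net_length_change % 3 != 0


@dataclass
class PtcCall:
    """Result of the downstream stop-codon scan for one variant."""

    found: bool
    ptc_cds_pos_variant: int | None = None  # first base of the stop, variant coords
    ptc_cds_pos_reference: int | None = None
    region: str | None = None
    escape_into_utr: bool = False


def apply_variant_to_cds(cds_sequence: str, variant: VariantAllele) -> str:
    """Edited coding sequence; the reading frame stays anchored at base 1."""
    seq = cds_sequence.upper()
    ref = variant.ref.upper()
    p = variant.cds_pos
    if not 1 <= p <= len(seq):
        raise ValueError(f"cds_pos {p} outside CDS of length {len(seq)}")
    if seq[p - 1 : p - 1 + len(ref)] != ref:
        raise ValueError(
            f"reference mismatch at cds_pos {p}: expected {ref!r}, "
            f"found {seq[p - 1 : p - 1 + len(ref)]!r}"
        )
    return seq[: p - 1] + variant.alt.upper() + seq[p - 1 + len(ref) :]


def scan_first_stop(variant_sequence: str, first_edited_pos: int) -> tuple[bool, int | None]:
    """First in-frame stop at or downstream of the edited codon.

    The frame is anchored at base 1 (the start codon); scanning begins at
    the codon containing ``first_edited_pos`` (variant coordinates).
    Returns (found, 1-based position of the stop codon's first base);
    ``found`` is False when the sequence ends without an in-frame stop.
    """
    seq = variant_sequence.upper()
    if first_edited_pos > len(seq):
        raise ValueError(
            f"edit position {first_edited_pos} beyond sequence of length {len(seq)}"
        )
    start = (first_edited_pos - 1) // 3 * 3
    for i in range(start, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return True, i + 1
    return False, None


def locate_ptc(
    cds_sequence: str,
    variant: VariantAllele,
    annotation: RegionAnnotation,
) -> PtcCall:
    """Apply a variant, find its downstream PTC and assign the NMD region.

    The PTC position is mapped back to reference coordinates by removing
    the variant's net length change when the stop lies downstream of the
    edit, so the region lookup happens on the reference annotation. An
    in-frame variant whose first downstream stop is the reference stop
    codon yields no PTC. Variants creating no stop before the end of the
    provided sequence are flagged ``escape_into_utr``.
    """
    cds_sequence = cds_sequence.upper()
    if len(cds_sequence) != annotation.cds_length:
        raise ValueError("sequence / annotation length mismatch")
    edited = apply_variant_to_cds(cds_sequence, variant)
    first_edited = variant.cds_pos if variant.variant_class != INSERTION else variant.cds_pos + 1
    first_edited = min(first_edited, len(edited))
    found, vpos = scan_first_stop(edited, first_edited)
    if not found:
        return PtcCall(found=False, escape_into_utr=True)

    # map back: subtract net inserted length 5' of the PTC (deletions add)
    net = variant.net_length_change
    edit_end_variant = variant.cds_pos - 1 + len(variant.alt)
    ref_pos = vpos - net if vpos >= edit_end_variant else vpos
    ref_stop_start = annotation.cds_length - 2
    if not variant.is_frameshift and ref_pos >= ref_stop_start:
        return PtcCall(found=False)  # reference stop reached: not premature
    if ref_pos > annotation.cds_length:
        return PtcCall(found=False, escape_into_utr=True)
    # Region anchor: when the edit itself lies inside the new stop codon
    # (an SNV or short indel creating the stop in place), the region is
    # read at the edited base, so the SNV pathway agrees exactly with the
    # positional annotation; for downstream stops the codon's first base
    # is the anchor.
    edit_start_variant = variant.cds_pos
    if edit_start_variant >= vpos and edit_start_variant <= vpos + 2:
        anchor_ref = variant.cds_pos
    else:
        anchor_ref = ref_pos
    return PtcCall(
        found=True,
        ptc_cds_pos_variant=vpos,
        ptc_cds_pos_reference=ref_pos,
        region=annotation.region_of(min(anchor_ref, annotation.cds_length)),
    )


def assign_ptc_region(
    ptc_call: PtcCall, variant: VariantAllele, annotation: RegionAnnotation
) -> str:
    """Region of an already-located PTC on the reference annotation."""
    if not ptc_call.found or ptc_call.ptc_cds_pos_reference is None:
        raise ValueError("no PTC located for this variant")
    return annotation.region_of(ptc_call.ptc_cds_pos_reference)
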