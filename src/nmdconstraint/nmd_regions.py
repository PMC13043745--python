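"""NMD region annotation over CDS coordinates.

A premature termination codon escapes nonsense-mediated decay when it falls

* within the first 150 nt of coding sequence (start-proximal),
* more than 400 nt upstream of the donor junction of its own exon (long
  exon), or
* in the last exon or the most 3' 50 nt of the penultimate exon (distal).

All remaining CDS positions are NMD targets. Positions carrying several
raw labels receive one definitive label with priority
start_proximal > distal > long_exon. Exon arithmetic is done in full
transcript exon space (UTR-only exons included), so transcripts with 3'UTR
introns are handled: when the CDS ends before the last exon, no CDS
position carries a last-exon label.

Distance convention: for CDS position p in an exon whose last coding base
has CDS coordinate J, d = J - p. long_exon requires d > 400 (strict);
the 50-nt rule requires d <= 49, i.e. exactly the last 50 coding bases of
the penultimate exon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from nmdconstraint.transcripts import TranscriptModel

START_PROXIMAL = "start_proximal"
LONG_EXON = "long_exon"
FIFTY_NT = "fifty_nt"
LAST_EXON = "last_exon"
DISTAL = "distal"
NMD_TARGET = "nmd_target"

#: final per-position labels, in priority order (highest first)
FINAL_LABELS = (START_PROXIMAL, DISTAL, LONG_EXON, NMD_TARGET)
ESCAPE_LABELS = (START_PROXIMAL, DISTAL, LONG_EXON)

START_PROXIMAL_WINDOW = 150
LONG_EXON_DISTANCE = 400
PENULTIMATE_WINDOW = 50


def _coding_span_per_exon(model: TranscriptModel) -> list[tuple[int, int, int]]:
    """(rank, cds_lo, cds_hi) for every exon with >=1 coding base.

    CDS coordinates are contiguous within an exon and across exons follow
    rank order, so cumulative coding lengths give each exon's CDS span.
    """
    spans = []
    offset = 0
    for ex in model.exons:
        n_coding = 0
        for s, e in model.cds_intervals:
            lo, hi = max(s, ex.start), min(e, ex.end)
            if lo <= hi:
                n_coding += hi - lo + 1
        if n_coding:
            spans.append((ex.rank, offset + 1, offset + n_coding))
            offset += n_coding
    if offset != model.cds_length:
        raise ValueError(
            f"transcript {model.transcript_id}: CDS bases outside exons "
            f"({offset} of {model.cds_length} accounted for)"
        )
    return spans


def annotate_raw_labels(
    model: TranscriptModel,
    *,
    start_window: int = START_PROXIMAL_WINDOW,
    long_exon_distance: int = LONG_EXON_DISTANCE,
    penultimate_window: int = PENULTIMATE_WINDOW,
) -> dict[str, np.ndarray]:
    """Raw (possibly overlapping) rule labels as boolean masks over cds_pos.

    Returns a dict keyed by {start_proximal, long_exon, fifty_nt, last_exon},
    each a boolean array of length cds_length (index 0 = cds_pos 1).
    """
    L = model.cds_length
    pos = np.arange(1, L + 1)
    labels = {k: np.zeros(L, dtype=bool) for k in (START_PROXIMAL, LONG_EXON, FIFTY_NT, LAST_EXON)}
    labels[START_PROXIMAL][: min(start_window, L)] = True

    n_exons = model.n_exons
    for rank, lo, hi in _coding_span_per_exon(model):
        in_exon = (pos >= lo) & (pos <= hi)
        if rank == n_exons:
            labels[LAST_EXON] |= in_exon
            continue
        # exon has a downstream intron; J = its last coding base
        d = hi - pos
        labels[LONG_EXON] |= in_exon & (d > long_exon_distance)
        if rank == n_exons - 1:
            labels[FIFTY_NT] |= in_exon & (d <= penultimate_window - 1)
    return labels


@dataclass
class RegionAnnotation:
    """Resolved per-position NMD labels for one transcript."""

    transcript_id: str
    labels: np.ndarray  # dtype object/str, length cds_length, values in FINAL_LABELS

    @property
    def cds_length(self) -> int:
        return len(self.labels)

    def region_lengths(self) -> dict[str, int]:
        return {r: int(np.sum(self.labels == r)) for r in FINAL_LABELS}

    def region_of(self, cds_pos: int) -> str:
        if not 1 <= cds_pos <= self.cds_length:
            raise KeyError(f"cds_pos {cds_pos} outside CDS of length {self.cds_length}")
        return str(self.labels[cds_pos - 1])

    def intervals(self) -> pd.DataFrame:
        """Merged per-region CDS intervals (1-based inclusive)."""
        rows = []
        lab = self.labels
        start = 0
        for i in range(1, len(lab) + 1):
            if i == len(lab) or lab[i] != lab[start]:
                rows.append(
                    {
                        "transcript_id": self.transcript_id,
                        "region": str(lab[start]),
                        "cds_start": start + 1,
                        "cds_end": i,
                    }
                )
                start = i
        return pd.DataFrame(rows)


def resolve_priority(transcript_id: str, raw_labels: dict[str, np.ndarray]) -> RegionAnnotation:
    """Collapse fifty_nt/last_exon to distal, then apply the priority order.

    Unlabelled positions become nmd_target.
    """
    L = len(raw_labels[START_PROXIMAL])
    final = np.full(L, NMD_TARGET, dtype=object)
    final[raw_labels[LONG_EXON]] = LONG_EXON
    final[raw_labels[FIFTY_NT] | raw_labels[LAST_EXON]] = DISTAL
    final[raw_labels[START_PROXIMAL]] = START_PROXIMAL
    return RegionAnnotation(transcript_id, final)


def annotate_regions(model: TranscriptModel, **rule_kwargs) -> RegionAnnotation:
    """Raw rules + priority resolution in one call."""
    return resolve_priority(model.transcript_id, annotate_raw_labels(model, **rule_kwargs))


def footprint_summary(annotations: list[RegionAnnotation]) -> dict:
    """Aggregate regional footprint over a transcript set.

    Returns per-region nucleotide totals and proportions of the pooled CDS,
    plus ``escape_proportion`` (start_proximal + long_exon + distal share).
    """
    if not annotations:
        raise ValueError("footprint_summary requires at least one annotation")
    totals = {r: 0 for r in FINAL_LABELS}
    for ann in annotations:
        for r, n in ann.region_lengths().items():
            totals[r] += n
    grand = sum(totals.values())
    props = {r: totals[r] / grand for r in FINAL_LABELS}
    return {
        "total_cds_nt": grand,
        "region_nt": totals,
        "region_proportion": props,
        "escape_proportion": sum(props[r] for r in ESCAPE_LABELS),
    }
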