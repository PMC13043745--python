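"""Canonical transcript models from GENCODE-dialect GTF.

Parses transcript/exon/CDS features, selects one representative transcript
per protein-coding gene (MANE Select where available, otherwise the APPRIS
principal isoform), and builds a bidirectional CDS <-> genome coordinate
map used by every positional rule downstream.

Coordinates are GTF-native: 1-based, inclusive at both ends. The in-memory
CDS *includes* the stop codon; GENCODE annotates the stop codon as a
separate ``stop_codon`` feature, which the reader merges into the CDS
intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MANE_SELECT = "MANE_Select"
APPRIS_PRINCIPAL = "APPRIS_principal"


class GtfParseError(ValueError):
    """Raised when a GTF line or transcript structure cannot be interpreted."""


@dataclass(frozen=True)
class ExonInterval:
    """One exon, 1-based inclusive genomic coordinates.

    ``rank`` counts exons 5'->3' in transcription order (rank 1 is the
    most 5' exon; on the minus strand that is the exon with the highest
    genomic coordinates).
    """

    chrom: str
    start: int
    end: int
    rank: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"exon start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    ``exons`` holds every exon (UTR-only exons included) ordered by rank.
    ``cds_intervals`` is the subset of genomic intervals covered by coding
    sequence (stop codon included), in transcription order.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[ExonInterval]
    cds_intervals: list[tuple[int, int]]
    source_tag: str | None = None
    gene_name: str | None = None

    cds_length: int = field(init=False)
    frame_ok: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r}")
        self.cds_length = sum(e - s + 1 for s, e in self.cds_intervals)
        self.frame_ok = self.cds_length > 0 and self.cds_length % 3 == 0
        if self.cds_length > 0 and not self.frame_ok:
            logger.warning(
                "transcript %s: CDS length %d not divisible by 3",
                self.transcript_id,
                self.cds_length,
            )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def has_utr3_intron(self) -> bool:
        """True iff at least one exon lies entirely 3' of the CDS end."""
        if not self.cds_intervals:
            return False
        last_cds_rank = self.exon_rank_of_cds_end()
        return last_cds_rank < self.n_exons

    def exon_rank_of_cds_end(self) -> int:
        """Rank of the exon containing the most 3' coding base."""
        s, e = self.cds_intervals[-1]
        end_pos = e if self.strand == "+" else s
        for ex in self.exons:
            if ex.start <= end_pos <= ex.end:
                return ex.rank
        raise GtfParseError(
            f"transcript {self.transcript_id}: CDS end {end_pos} outside all exons"
        )


class CdsMap:
    """Bijection between CDS coordinates (1..cds_length) and genomic positions.

    cds_pos 1 is the first base of the start codon; positions increase
    5'->3' along the coding strand.
    """

    def __init__(self, chrom: str, genomic_positions: np.ndarray):
        self.chrom = chrom
        self._g = np.asarray(genomic_positions, dtype=np.int64)
        if len(np.unique(self._g)) != len(self._g):
            raise GtfParseError("overlapping CDS intervals: duplicate genomic positions")
        self._inv = {int(g): i + 1 for i, g in enumerate(self._g)}

    def __len__(self) -> int:
        return len(self._g)

    def to_genomic(self, cds_pos: int) -> int:
        if not 1 <= cds_pos <= len(self._g):
            raise KeyError(f"cds_pos {cds_pos} outside CDS of length {len(self._g)}")
        return int(self._g[cds_pos - 1])

    def to_cds(self, genomic_pos: int) -> int:
        try:
            return self._inv[int(genomic_pos)]
        except KeyError:
            raise KeyError(f"genomic position {genomic_pos} not in CDS") from None

    @property
    def genomic_positions(self) -> np.ndarray:
        """Genomic positions in CDS order (read-only view)."""
        v = self._g.view()
        v.flags.writeable = False
        return v


def build_cds_map(model: TranscriptModel) -> CdsMap:
    """Build the CDS<->genome map for ``model``.

    Intervals are concatenated in transcription order; on the minus strand
    positions within each interval run from the interval end downward.
    """
    if not model.cds_intervals:
        raise GtfParseError(f"transcript {model.transcript_id} has no CDS")
    chunks = []
    for s, e in model.cds_intervals:
        if model.strand == "+":
            chunks.append(np.arange(s, e + 1, dtype=np.int64))
        else:
            chunks.append(np.arange(e, s - 1, -1, dtype=np.int64))
    return CdsMap(model.chrom, np.concatenate(chunks))


def _merge_adjacent(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals, merging overlaps and abutments."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [ivs[0]]
    for s, e in ivs[1:]:
        ps, pe = out[-1]
        if s <= pe + 1:
            out[-1] = (ps, max(pe, e))
        else:
            out.append((s, e))
    return out


def _attr_matches(attrs: Mapping[str, Sequence[str]], key: str, wanted: str) -> bool:
    # GENCODE repeats the `tag` key; gffutils keeps every value.
    return wanted in attrs.get(key, ())


def read_gtf_transcripts(
    gtf_path: str,
    attribute_filters: Mapping[str, str] | None = None,
) -> list[TranscriptModel]:
    """Read a GENCODE-dialect GTF into :class:`TranscriptModel` objects.

    Parameters
    ----------
    gtf_path
        Path to an uncompressed or gzipped GTF file.
    attribute_filters
        Mapping attribute -> required value applied to *transcript* features
        (e.g. ``{"tag": "Ensembl_canonical", "gene_type": "protein_coding",
        "transcript_type": "protein_coding"}``). For multi-valued attributes
        such as ``tag`` the filter checks membership.

    Returns
    -------
    One model per transcript that passes every filter, with exon ranks in
    transcription order and CDS intervals merged with the stop codon.
    """
    attribute_filters = dict(attribute_filters or {})
    with open(gtf_path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return []  # empty annotation: no transcripts
    try:
        db = gffutils.create_db(
            str(gtf_path),
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises heterogeneous parse errors
        raise GtfParseError(f"failed to parse GTF {gtf_path}: {exc}") from exc

    # exon / CDS / stop_codon features grouped by transcript_id
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    for feat in db.all_features():
        if feat.featuretype not in {"exon", "CDS", "stop_codon"}:
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            raise GtfParseError(
                f"{feat.featuretype} feature at {feat.seqid}:{feat.start} lacks transcript_id"
            )
        bucket = exons if feat.featuretype == "exon" else cds
        bucket.setdefault(tid, []).append((feat.start, feat.end))

    models: list[TranscriptModel] = []
    for feat in db.features_of_type("transcript"):
        attrs = feat.attributes
        tid = attrs["transcript_id"][0]
        if not all(_attr_matches(attrs, k, v) for k, v in attribute_filters.items()):
            continue
        tx_exons = exons.get(tid, [])
        tx_cds = _merge_adjacent(cds.get(tid, []))
        if tx_cds and not tx_exons:
            raise GtfParseError(f"transcript {tid} has CDS but no exons")
        if not tx_cds:
            continue  # non-coding transcript: out of scope
        strand = feat.strand
        ordered = sorted(tx_exons, reverse=(strand == "-"))
        exon_objs = [
            ExonInterval(feat.seqid, s, e, rank=i + 1) for i, (s, e) in enumerate(ordered)
        ]
        cds_ordered = sorted(tx_cds, reverse=(strand == "-"))
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=attrs["gene_id"][0],
                chrom=feat.seqid,
                strand=strand,
                exons=exon_objs,
                cds_intervals=cds_ordered,
                gene_name=attrs.get("gene_name", [None])[0],
            )
        )
    return models


def select_canonical(
    models: Iterable[TranscriptModel],
    mane_ids: Iterable[str],
    appris_ids: Iterable[str],
) -> list[TranscriptModel]:
    """Pick one representative transcript per gene.

    MANE Select is preferred; genes without a MANE transcript fall back to
    the APPRIS principal isoform; genes with neither are dropped and logged.
    Selection is deterministic and independent of input order.
    """
    mane = set(mane_ids)
    appris = set(appris_ids)
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in sorted(models, key=lambda m: m.transcript_id):
        by_gene.setdefault(m.gene_id, []).append(m)

    selected: list[TranscriptModel] = []
    for gene_id in sorted(by_gene):
        txs = by_gene[gene_id]
        mane_hits = [t for t in txs if t.transcript_id in mane]
        if len(mane_hits) > 1:
            raise ValueError(
                f"gene {gene_id}: multiple MANE Select transcripts "
                f"{[t.transcript_id for t in mane_hits]}"
            )
        if mane_hits:
            chosen = mane_hits[0]
            chosen.source_tag = MANE_SELECT
        else:
            appris_hits = [t for t in txs if t.transcript_id in appris]
            if not appris_hits:
                logger.info("gene %s: no MANE or APPRIS transcript; dropped", gene_id)
                continue
            chosen = appris_hits[0]
            chosen.source_tag = APPRIS_PRINCIPAL
        selected.append(chosen)
    return selected


def transcript_table(models: Iterable[TranscriptModel]) -> pd.DataFrame:
    """Summary table of selected transcripts (TSV-ready)."""
    rows = [
        {
            "transcript_id": m.transcript_id,
            "gene_id": m.gene_id,
            "strand": m.strand,
            "n_exons": m.n_exons,
            "cds_length": m.cds_length,
            "source_tag": m.source_tag or "",
        }
        for m in models
    ]
    return pd.DataFrame(rows)
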