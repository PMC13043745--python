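"""Shared fixtures: hand-built toy transcripts and a small synthetic study."""

from __future__ import annotations

import pytest

from nmdconstraint.synthetic_data import SimConfig, simulate_transcriptome
from nmdconstraint.transcripts import ExonInterval, TranscriptModel


def make_model(
    coding_lens,
    strand: str = "+",
    *,
    utr5: int = 0,
    utr3_same_exon: int = 0,
    utr3_exon_len: int = 0,
    chrom: str = "chr1",
    start: int = 1001,
    intron: int = 100,
    tid: str = "TX1",
    gid: str = "G1",
) -> TranscriptModel:
    """Toy transcript with the given coding-exon lengths (5'->3').

    ``utr5`` prepends UTR to the first exon, ``utr3_same_exon`` appends
    UTR to the last coding exon, ``utr3_exon_len`` adds a UTR-only final
    exon (creating a 3'UTR intron).
    """
    exon_lens = list(coding_lens)
    exon_lens[0] += utr5
    exon_lens[-1] += utr3_same_exon
    if utr3_exon_len:
        exon_lens.append(utr3_exon_len)
    n = len(exon_lens)
    order = range(n) if strand == "+" else range(n - 1, -1, -1)
    pos = start
    genomic: dict[int, tuple[int, int]] = {}
    for idx in order:
        L = exon_lens[idx]
        genomic[idx] = (pos, pos + L - 1)
        pos += L + intron
    exons = [ExonInterval(chrom, *genomic[i], rank=i + 1) for i in range(n)]
    n_coding = len(coding_lens)
    cds = []
    for i in range(n_coding):
        s, e = genomic[i]
        lead = utr5 if i == 0 else 0
        trail = utr3_same_exon if i == n_coding - 1 else 0
        if strand == "+":
            cds.append((s + lead, e - trail))
        else:
            cds.append((s + trail, e - lead))
    cds.sort(reverse=(strand == "-"))
    return TranscriptModel(tid, gid, chrom, strand, exons, cds)


@pytest.fixture(scope="session")
def small_study():
    """12-transcript synthetic study with an elevated 3'UTR-intron fraction."""
    return simulate_transcriptome(SimConfig(seed=5, n_transcripts=12, utr3_intron_fraction=0.3))
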