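"""Positional NMD rules, priority resolution and footprint arithmetic."""

import numpy as np
import pytest

from nmdconstraint.nmd_regions import (
    DISTAL,
    FIFTY_NT,
    LAST_EXON,
    LONG_EXON,
    NMD_TARGET,
    START_PROXIMAL,
    annotate_raw_labels,
    annotate_regions,
    footprint_summary,
    resolve_priority,
)

from conftest import make_model


def mask_span(mask):
    """1-based (start, end) spans of True runs in a boolean mask."""
    idx = np.nonzero(mask)[0] + 1
    if len(idx) == 0:
        return []
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(idx) - 1]])
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


class TestRawLabels:
    def test_three_equal_exons(self):
        """3 x 300 nt coding exons: forced raw intervals for every rule."""
        raw = annotate_raw_labels(make_model([300, 300, 300]))
        assert mask_span(raw[START_PROXIMAL]) == [(1, 150)]
        assert mask_span(raw[FIFTY_NT]) == [(551, 600)]
        assert mask_span(raw[LAST_EXON]) == [(601, 900)]
        assert mask_span(raw[LONG_EXON]) == []

    def test_long_first_exon(self):
        """600/100/100 exons: long-exon label is >400 nt upstream of the donor."""
        raw = annotate_raw_labels(make_model([600, 100, 100]))
        assert mask_span(raw[LONG_EXON]) == [(1, 199)]
        assert mask_span(raw[FIFTY_NT]) == [(651, 700)]
        assert mask_span(raw[LAST_EXON]) == [(701, 800)]

    def test_utr3_intron_removes_last_exon_label(self):
        """CDS confined to the penultimate exon: no last-exon label, but the
        most 3' 50 coding bases still satisfy the 50-nt rule."""
        m = make_model([300], utr3_same_exon=40, utr3_exon_len=120)
        raw = annotate_raw_labels(m)
        assert m.has_utr3_intron
        assert mask_span(raw[LAST_EXON]) == []
        assert mask_span(raw[FIFTY_NT]) == [(251, 300)]

    def test_utr3_intron_two_exons_back_no_fifty_nt(self):
        """When the CDS ends two exons before the transcript end, neither the
        last-exon nor the 50-nt rule applies to coding positions."""
        m = make_model([300], utr3_exon_len=120)
        # add a second UTR exon by appending to the exon list via builder:
        m2 = make_model([300], utr3_exon_len=100)
        raw2 = annotate_raw_labels(m2)
        assert mask_span(raw2[FIFTY_NT]) == [(251, 300)]  # coding exon is penultimate
        # three-exon case: coding exon is ante-penultimate
        from nmdconstraint.transcripts import ExonInterval, TranscriptModel

        exons = [e for e in m.exons]
        last = exons[-1]
        exons.append(ExonInterval(last.chrom, last.end + 101, last.end + 180, rank=len(exons) + 1))
        m3 = TranscriptModel("TX3", "G1", m.chrom, "+", exons, m.cds_intervals)
        raw3 = annotate_raw_labels(m3)
        assert mask_span(raw3[FIFTY_NT]) == []
        assert mask_span(raw3[LAST_EXON]) == []
        # its donor junction still triggers the long-exon rule when far enough
        assert mask_span(raw3[LONG_EXON]) == []  # 300 nt exon: never >400 from donor

    def test_long_exon_before_utr3_intron(self):
        """A long final-coding exon followed by a 3'UTR intron has a real
        donor site, so its 5' positions are long-exon labelled."""
        m = make_model([600], utr3_exon_len=150)
        raw = annotate_raw_labels(m)
        assert mask_span(raw[LONG_EXON]) == [(1, 199)]

    def test_strand_invariance(self):
        """A transcript and its minus-strand mirror produce identical labels."""
        for lens in ([300, 300, 300], [600, 100, 100]):
            plus = annotate_regions(make_model(lens, "+"))
            minus = annotate_regions(make_model(lens, "-"))
            assert np.array_equal(plus.labels, minus.labels)


class TestPriority:
    def test_start_proximal_beats_distal(self):
        L = 120
        raw = {
            START_PROXIMAL: np.ones(L, bool),
            LONG_EXON: np.zeros(L, bool),
            FIFTY_NT: np.zeros(L, bool),
            LAST_EXON: np.ones(L, bool),
        }
        ann = resolve_priority("T", raw)
        assert set(ann.labels) == {START_PROXIMAL}

    def test_distal_beats_long_exon(self):
        L = 60
        raw = {k: np.zeros(L, bool) for k in (START_PROXIMAL, LONG_EXON, FIFTY_NT, LAST_EXON)}
        raw[LONG_EXON][:] = True
        raw[FIFTY_NT][30:] = True
        ann = resolve_priority("T", raw)
        assert set(ann.labels[:30]) == {LONG_EXON}
        assert set(ann.labels[30:]) == {DISTAL}

    def test_unlabelled_is_nmd_target(self):
        raw = {k: np.zeros(9, bool) for k in (START_PROXIMAL, LONG_EXON, FIFTY_NT, LAST_EXON)}
        assert set(resolve_priority("T", raw).labels) == {NMD_TARGET}

    def test_resolved_three_exon_intervals(self):
        ann = annotate_regions(make_model([300, 300, 300]))
        iv = ann.intervals()
        assert list(map(tuple, iv[["region", "cds_start", "cds_end"]].itertuples(index=False))) == [
            (START_PROXIMAL, 1, 150),
            (NMD_TARGET, 151, 550),
            (DISTAL, 551, 900),
        ]


class TestInvariantsAndFootprint:
    def test_region_lengths_sum_to_cds_length(self, small_study):
        for tid, ann in small_study.annotations.items():
            assert sum(ann.region_lengths().values()) == ann.cds_length

    def test_single_exon_transcript_labels(self):
        """Single coding exon, no 3'UTR introns: only start-proximal/distal."""
        ann = annotate_regions(make_model([300]))
        assert set(ann.labels) <= {START_PROXIMAL, DISTAL}
        short = annotate_regions(make_model([150]))
        assert set(short.labels) == {START_PROXIMAL}

    def test_removing_utr3_intron_only_grows_distal(self):
        with_intron = annotate_regions(make_model([300, 300], utr3_exon_len=100))
        without = annotate_regions(make_model([300, 300]))
        n_with = with_intron.region_lengths()
        n_without = without.region_lengths()
        assert n_without[DISTAL] >= n_with[DISTAL]
        assert n_without[START_PROXIMAL] == n_with[START_PROXIMAL]

    def test_footprint_arithmetic(self):
        ann = annotate_regions(make_model([300, 300, 300]))
        fp = footprint_summary([ann])
        assert fp["total_cds_nt"] == 900
        assert fp["escape_proportion"] == pytest.approx((150 + 350) / 900)
        assert sum(fp["region_proportion"].values()) == pytest.approx(1.0, abs=1e-12)

    def test_footprint_empty_input_errors(self):
        with pytest.raises(ValueError):
            footprint_summary([])
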