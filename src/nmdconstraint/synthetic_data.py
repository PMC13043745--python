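"""Statistically controlled synthetic fixtures for the whole pipeline.

Generates a small transcriptome (GENCODE-dialect GTF + genome FASTA) with
multi-exon structures and a configurable fraction of 3'UTR introns,
assigns every possible CDS SNV a raw mutation rate from a log-normal
mixture, simulates a population cohort (Bernoulli site observation with
region-specific selection against nonsense variants, and an allele-count
spectrum whose singleton proportion rises with selection), and simulates
trio de novo variants (Poisson counts proportional to mutation rate with
regional enrichment, random 1-2 nt frameshifts, and a logistic
case-solved outcome model with a configurable carrier odds ratio).

Every draw flows from one ``numpy`` generator seeded in the config, so
outputs are byte-identical across runs. The generator emulates the
*statistical* structure the analyses assume — rate heterogeneity,
depth-dependent ascertainment, selection-dependent frequency spectra —
not human genome realism (no demography, no sequence-context mutation
model, no linkage).
"""

from __future__ import annotations

import json
import textwrap
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from nmdconstraint.consequences import NONSENSE, enumerate_possible_snvs
from nmdconstraint.nmd_regions import FINAL_LABELS, RegionAnnotation, annotate_regions
from nmdconstraint.ptc_locate import VariantAllele, locate_ptc
from nmdconstraint.transcripts import CdsMap, ExonInterval, TranscriptModel, build_cds_map

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in {"TAA", "TAG", "TGA"}
]
_STOPS = ["TAA", "TAG", "TGA"]
_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the structure of the real study inputs at desk scale:
    multi-exon transcripts with ~4% 3'UTR introns, a heavy-tailed
    mutation-rate distribution, a cohort scale giving a mean neutral
    observation probability near 0.15 (of the order of the fraction of
    possible coding SNVs segregating in a biobank-scale cohort), a
    baseline singleton proportion of 0.45, and trio DNV intensities small
    enough that de novo events are rare per site.
    """

    seed: int
    n_transcripts: int = 60
    # transcript structure
    exon_count_mean: float = 5.0
    exon_length_log_mean: float = 5.1  # exp ~ 165 nt coding per exon
    exon_length_log_sd: float = 0.7
    min_exon_coding: int = 30
    utr3_intron_fraction: float = 0.04
    minus_strand_fraction: float = 0.5
    intron_length_range: tuple[int, int] = (80, 300)
    utr5_max: int = 90
    # raw mutation rates: two-component log-normal mixture
    rate_mix_weight: float = 0.9
    rate_log_mean: tuple[float, float] = (0.0, 1.4)
    rate_log_sd: tuple[float, float] = (0.55, 0.55)
    # cohort observation model
    cohort_lambda: float = 0.12
    s_region: dict[str, float] = field(default_factory=dict)  # region -> fraction removed
    low_depth_fraction: float = 0.05
    depth_low: int = 10
    depth_high: int = 32
    # allele-count / singleton model: the singleton proportion falls
    # linearly with the neutral observation probability (more mutable
    # sites segregate at higher frequency) and rises with selection
    singleton_base: float = 0.45
    singleton_delta: float = 0.4
    singleton_rate_slope: float = 0.5
    ac_geom_p: float = 0.4
    # trio DNV model; defaults give of the order of 1e-4 coding DNVs per
    # gene per trio, the scale seen in large rare-disease trio cohorts
    n_trios: int = 5000
    dnv_nu: float = 3e-8
    e_region: dict[str, float] = field(default_factory=dict)  # region -> PTV enrichment
    frameshift_per_kb_per_trio: float = 5e-6
    solved_baseline: float = 0.3
    carrier_or: float = 1.0

    def selection(self, region: str) -> float:
        return float(self.s_region.get(region, 0.0))

    def enrichment(self, region: str) -> float:
        return float(self.e_region.get(region, 1.0))


@dataclass
class SimulatedStudy:
    """In-memory fixture bundle produced by :func:`simulate_transcriptome`."""

    config: SimConfig
    models: list[TranscriptModel]
    cds_sequences: dict[str, str]
    genome: dict[str, str]
    annotations: dict[str, RegionAnnotation]
    cds_maps: dict[str, CdsMap]
    possible_snvs: pd.DataFrame  # incl. raw_rate column

    # ---- writers ----------------------------------------------------

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write GTF, FASTA, rate table and id lists; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gtf": outdir / "annotation.gtf",
            "fasta": outdir / "genome.fa",
            "rates": outdir / "rates.tsv",
            "mane": outdir / "mane_ids.txt",
            "appris": outdir / "appris_ids.txt",
        }
        self.write_gtf(paths["gtf"])
        self.write_fasta(paths["fasta"])
        self.possible_snvs[["chrom", "pos", "ref", "alt", "raw_rate"]].to_csv(
            paths["rates"], sep="\t", index=False
        )
        paths["mane"].write_text("".join(m.transcript_id + "\n" for m in self.models))
        paths["appris"].write_text("")
        return paths

    def write_gtf(self, path: str | Path) -> None:
        """GENCODE-dialect GTF; CDS features exclude the stop codon, which
        is written as a separate stop_codon feature (as GENCODE does)."""
        lines = []
        for m in self.models:
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'gene_type "protein_coding"; transcript_type "protein_coding"; '
                f'tag "Ensembl_canonical";'
            )
            tx_start = min(e.start for e in m.exons)
            tx_end = max(e.end for e in m.exons)

            def row(feature, start, end):
                lines.append(
                    f"{m.chrom}\tsim\t{feature}\t{start}\t{end}\t.\t{m.strand}\t.\t{attrs}"
                )

            row("gene", tx_start, tx_end)
            row("transcript", tx_start, tx_end)
            for e in m.exons:
                row("exon", e.start, e.end)
            cmap = self.cds_maps[m.transcript_id]
            L = m.cds_length
            coding = cmap.genomic_positions[: L - 3]
            stop = cmap.genomic_positions[L - 3 :]
            for s, e in _runs(np.sort(coding)):
                row("CDS", s, e)
            for s, e in _runs(np.sort(stop)):
                row("stop_codon", s, e)
        Path(path).write_text("\n".join(lines) + "\n")

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                fh.write("\n".join(textwrap.wrap(self.genome[chrom], 60)) + "\n")


def _runs(sorted_positions: np.ndarray):
    """Contiguous (start, end) runs of sorted 1-based positions."""
    if len(sorted_positions) == 0:
        return
    breaks = np.nonzero(np.diff(sorted_positions) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(sorted_positions) - 1]])
    for s, e in zip(starts, ends):
        yield int(sorted_positions[s]), int(sorted_positions[e])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """'ATG' + sense codons + one stop; no internal in-frame stop."""
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + stop


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def simulate_transcriptome(config: SimConfig) -> SimulatedStudy:
    """Build the synthetic transcriptome and its possible-SNV table."""
    rng = np.random.default_rng(config.seed)
    chrom = "chrS"
    genome_parts: list[str] = []
    cursor = 1  # next free 1-based genomic coordinate
    models: list[TranscriptModel] = []
    cds_sequences: dict[str, str] = {}

    for t in range(config.n_transcripts):
        tid = f"SIMT{t:05d}"
        gid = f"SIMG{t:05d}"
        n_coding = max(1, int(rng.poisson(config.exon_count_mean - 1)) + 1)
        coding_lens = np.maximum(
            config.min_exon_coding,
            np.rint(rng.lognormal(config.exon_length_log_mean, config.exon_length_log_sd, n_coding)).astype(int),
        )
        total = int(coding_lens.sum())
        total -= total % 3
        if total < 9:
            total = 9
        # re-balance so coding lengths sum to a multiple of 3
        coding_lens[-1] += total - int(coding_lens.sum())
        if coding_lens[-1] < 3:
            coding_lens[-1] += 3
            total += 3
        cds_seq = _random_cds(rng, total // 3)
        cds_sequences[tid] = cds_seq

        utr5 = int(rng.integers(0, config.utr5_max + 1))
        has_utr3_intron = rng.random() < config.utr3_intron_fraction
        utr3_same_exon = int(rng.integers(20, 120))
        # transcript-space exon lengths
        exon_t_lens = list(coding_lens)
        exon_t_lens[0] += utr5
        exon_t_lens[-1] += utr3_same_exon
        if has_utr3_intron:
            exon_t_lens.append(int(rng.integers(60, 200)))  # UTR-only final exon
        mrna = (
            _random_seq(rng, utr5)
            + cds_seq
            + _random_seq(rng, sum(exon_t_lens) - utr5 - len(cds_seq))
        )

        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        lo, hi = config.intron_length_range
        introns = [int(rng.integers(lo, hi + 1)) for _ in range(len(exon_t_lens) - 1)]

        # lay exons onto the genome; transcript order == genomic order on +,
        # reversed on -
        t_off = 0
        segs = []
        for L in exon_t_lens:
            segs.append(mrna[t_off : t_off + L])
            t_off += L
        order = range(len(segs)) if strand == "+" else range(len(segs) - 1, -1, -1)
        g_intervals: dict[int, tuple[int, int]] = {}
        block_parts = []
        pos = cursor
        for j, idx in enumerate(order):
            seg = segs[idx] if strand == "+" else _revcomp(segs[idx])
            g_intervals[idx] = (pos, pos + len(seg) - 1)
            block_parts.append(seg)
            pos += len(seg)
            if j < len(segs) - 1:
                ilen = introns[j]
                block_parts.append(_random_seq(rng, ilen))
                pos += ilen
        gap = _random_seq(rng, 100)
        genome_parts.append("".join(block_parts) + gap)
        cursor = pos + 100

        exons = [
            ExonInterval(chrom, *g_intervals[idx], rank=i + 1)
            for i, idx in enumerate(range(len(segs)))
        ]
        # CDS genomic intervals: per coding exon, the coding sub-interval
        cds_intervals = []
        for i in range(n_coding):
            s, e = g_intervals[i]
            lead = utr5 if i == 0 else 0
            trail = utr3_same_exon if i == n_coding - 1 else 0
            if strand == "+":
                cds_intervals.append((s + lead, e - trail))
            else:
                cds_intervals.append((s + trail, e - lead))
        cds_intervals.sort(reverse=(strand == "-"))
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds_intervals=cds_intervals,
            )
        )

    genome = {chrom: "".join(genome_parts)}
    annotations = {m.transcript_id: annotate_regions(m) for m in models}
    cds_maps = {m.transcript_id: build_cds_map(m) for m in models}

    frames = [
        enumerate_possible_snvs(
            m, cds_sequences[m.transcript_id], annotations[m.transcript_id], cds_maps[m.transcript_id]
        )
        for m in models
    ]
    snvs = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=[
                "chrom", "pos", "ref", "alt", "transcript_id", "gene_id",
                "cds_pos", "cds_ref", "cds_alt", "consequence", "region",
            ]
        )
    )
    snvs["raw_rate"] = _draw_raw_rates(rng, len(snvs), config)
    return SimulatedStudy(config, models, cds_sequences, genome, annotations, cds_maps, snvs)


def _draw_raw_rates(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    hot = rng.random(n) >= config.rate_mix_weight
    mu = np.where(hot, config.rate_log_mean[1], config.rate_log_mean[0])
    sd = np.where(hot, config.rate_log_sd[1], config.rate_log_sd[0])
    return np.exp(rng.normal(mu, sd))


def simulate_cohort(
    study: SimulatedStudy, seed_offset: int = 1, config: SimConfig | None = None
) -> pd.DataFrame:
    """Bernoulli site observation with region-specific nonsense selection.

    Returns the possible-SNV table with neutral_prob, observed,
    allele_count and median_depth columns. Observation probability is
    min(1, lambda * raw_rate), multiplied by (1 - s_region) for nonsense
    SNVs; allele counts are zero-truncated with a singleton probability
    that increases with selection.
    """
    cfg = config or study.config
    rng = np.random.default_rng(cfg.seed + seed_offset)
    df = study.possible_snvs.copy()
    neutral = np.clip(cfg.cohort_lambda * df["raw_rate"].to_numpy(), 0.0, 1.0)
    s = np.array([cfg.selection(r) for r in FINAL_LABELS])
    region_idx = pd.Categorical(df["region"], categories=list(FINAL_LABELS)).codes
    keep_frac = np.where(df["consequence"].to_numpy() == NONSENSE, 1.0 - s[region_idx], 1.0)
    p_obs = neutral * keep_frac
    df["neutral_prob"] = neutral
    df["observed"] = rng.random(len(df)) < p_obs

    # allele counts: AC=1 with prob p1(s); otherwise 1 + (1 + geometric)
    p1 = np.clip(
        cfg.singleton_base
        - cfg.singleton_rate_slope * neutral
        + cfg.singleton_delta * s[region_idx] * (df["consequence"].to_numpy() == NONSENSE),
        0.0,
        1.0,
    )
    ac = np.zeros(len(df), dtype=int)
    obs = df["observed"].to_numpy()
    singleton = rng.random(len(df)) < p1
    ac[obs & singleton] = 1
    n_big = int((obs & ~singleton).sum())
    ac[obs & ~singleton] = 1 + rng.geometric(cfg.ac_geom_p, size=n_big)
    df["allele_count"] = ac

    # site depth, shared across the 3 alleles of a position
    sites = df.groupby(["chrom", "pos"], observed=True, sort=True).size().index
    low = rng.random(len(sites)) < cfg.low_depth_fraction
    depth = pd.Series(
        np.where(low, cfg.depth_low, cfg.depth_high), index=sites, name="median_depth"
    )
    df = df.merge(depth.reset_index(), on=["chrom", "pos"], how="left")
    return df


def simulate_trios(
    study: SimulatedStudy, seed_offset: int = 2, config: SimConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trio DNVs and case-solved outcomes.

    SNV DNV counts are Poisson(nu * raw_rate * e_region) for nonsense
    (e_region = 1 for synonymous/missense); frameshifts are random 1-2 nt
    indels thinned by the enrichment of their *downstream PTC* region.
    Each DNV is assigned to a random proband; a proband carrying a
    truncating DNV in an enriched region (e_region > 1) is solved with
    odds multiplied by ``carrier_or``.
    """
    cfg = config or study.config
    rng = np.random.default_rng(cfg.seed + seed_offset)
    snvs = study.possible_snvs
    e = np.array([cfg.enrichment(r) for r in FINAL_LABELS])
    region_idx = pd.Categorical(snvs["region"], categories=list(FINAL_LABELS)).codes
    mult = np.where(snvs["consequence"].to_numpy() == NONSENSE, e[region_idx], 1.0)
    lam = cfg.dnv_nu * snvs["raw_rate"].to_numpy() * mult * cfg.n_trios
    counts = rng.poisson(lam)
    idx = np.repeat(np.arange(len(snvs)), counts)
    dnv = snvs.iloc[idx][
        ["chrom", "pos", "ref", "alt", "transcript_id", "gene_id", "cds_pos", "consequence", "region"]
    ].reset_index(drop=True)

    # frameshift DNVs: uniform positions, PTC-relocated region, thinned by e
    fs_rows = []
    e_max = max(e.max(), 1.0)
    for m in study.models:
        n_fs = rng.poisson(cfg.frameshift_per_kb_per_trio * m.cds_length / 1000 * cfg.n_trios)
        ann = study.annotations[m.transcript_id]
        seq = study.cds_sequences[m.transcript_id]
        for _ in range(n_fs):
            p = int(rng.integers(1, max(2, m.cds_length - 3)))
            if rng.random() < 0.5:
                ins = _random_seq(rng, int(rng.integers(1, 3)))
                var = VariantAllele(m.transcript_id, p, seq[p - 1], seq[p - 1] + ins)
            else:
                ndel = int(rng.integers(1, 3))
                if p + ndel > m.cds_length:
                    continue
                var = VariantAllele(m.transcript_id, p, seq[p - 1 : p + ndel], seq[p - 1])
            call = locate_ptc(seq, var, ann)
            if not call.found:
                continue
            accept = cfg.enrichment(call.region) / e_max
            if rng.random() >= accept:
                continue
            cmap = study.cds_maps[m.transcript_id]
            fs_rows.append(
                {
                    "chrom": m.chrom,
                    "pos": cmap.to_genomic(p),
                    "ref": var.ref,
                    "alt": var.alt,
                    "transcript_id": m.transcript_id,
                    "gene_id": m.gene_id,
                    "cds_pos": p,
                    "consequence": "frameshift",
                    "region": call.region,
                }
            )
    if fs_rows:
        dnv = pd.concat([dnv, pd.DataFrame(fs_rows)], ignore_index=True)

    dnv["proband_id"] = [f"P{int(i):06d}" for i in rng.integers(0, cfg.n_trios, size=len(dnv))]
    dnv["cohort"] = "SIM"

    # outcome model: logistic in carrier status
    enriched_regions = {r for r in FINAL_LABELS if cfg.enrichment(r) > 1.0}
    carrier_probands = set(
        dnv.loc[
            dnv["consequence"].isin(["nonsense", "frameshift"])
            & dnv["region"].isin(enriched_regions),
            "proband_id",
        ]
    )
    probands = [f"P{i:06d}" for i in range(cfg.n_trios)]
    base_odds = cfg.solved_baseline / (1.0 - cfg.solved_baseline)
    odds = np.array(
        [base_odds * (cfg.carrier_or if p in carrier_probands else 1.0) for p in probands]
    )
    p_solved = odds / (1.0 + odds)
    solved = rng.random(cfg.n_trios) < p_solved
    outcomes = pd.DataFrame(
        {"proband_id": probands, "case_solved": np.where(solved, "yes", "no")}
    )
    return dnv, outcomes


def write_truth(config: SimConfig, path: str | Path) -> None:
    """Serialise the generator's ground truth for downstream checks."""
    truth = {
        "s_region": config.s_region,
        "e_region": config.e_region,
        "carrier_or": config.carrier_or,
        "seed": config.seed,
    }
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
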