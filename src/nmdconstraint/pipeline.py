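"""File-level orchestration: from GTF/FASTA/TSV inputs to result tables.

Thin glue used by the CLI and the examples: loads transcript models and
sequences, enumerates and annotates possible SNVs, joins rate / cohort /
depth tables, and runs calibration and constraint. All heavy lifting
lives in the per-step modules.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from pyfaidx import Fasta

from nmdconstraint import consequences, constraint, mutation_model, nmd_regions, transcripts

logger = logging.getLogger(__name__)

CANONICAL_FILTERS = {
    "tag": "Ensembl_canonical",
    "gene_type": "protein_coding",
    "transcript_type": "protein_coding",
}

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass
class LoadedStudy:
    models: list[transcripts.TranscriptModel]
    cds_sequences: dict[str, str]
    annotations: dict[str, nmd_regions.RegionAnnotation]
    cds_maps: dict[str, transcripts.CdsMap]


def cds_sequence_from_fasta(model: transcripts.TranscriptModel, fasta: Fasta) -> str:
    """Coding-strand CDS sequence (stop codon included) from a genome FASTA."""
    parts = []
    for s, e in sorted(model.cds_intervals):
        parts.append(str(fasta[model.chrom][s - 1 : e]).upper())
    seq = "".join(parts)
    if model.strand == "-":
        seq = seq.translate(_COMP)[::-1]
    return seq


def load_study(
    gtf_path: str,
    fasta_path: str,
    mane_path: str | None = None,
    appris_path: str | None = None,
    attribute_filters: dict | None = CANONICAL_FILTERS,
) -> LoadedStudy:
    """Read annotation + genome and build models, maps and region labels."""
    models = transcripts.read_gtf_transcripts(gtf_path, attribute_filters)
    if mane_path is not None:
        mane = _read_id_list(mane_path)
        appris = _read_id_list(appris_path) if appris_path else set()
        models = transcripts.select_canonical(models, mane, appris)
    fasta = Fasta(str(fasta_path))
    seqs = {m.transcript_id: cds_sequence_from_fasta(m, fasta) for m in models}
    annotations = {m.transcript_id: nmd_regions.annotate_regions(m) for m in models}
    maps = {m.transcript_id: transcripts.build_cds_map(m) for m in models}
    return LoadedStudy(models, seqs, annotations, maps)


def _read_id_list(path: str) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def build_snv_table(
    study: LoadedStudy,
    rates: pd.DataFrame,
    cohort: pd.DataFrame | None = None,
    depths: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Possible-SNV table with raw rates, observation flags and depths.

    ``cohort`` holds observed sites (chrom, pos, ref, alt, allele_count);
    possible SNVs absent from it are unobserved. ``depths`` holds
    per-site median depth; sites missing from it default to high coverage.
    """
    frames = []
    for m in study.models:
        if not m.frame_ok:
            logger.warning("skipping %s: CDS length not divisible by 3", m.transcript_id)
            continue
        frames.append(
            consequences.enumerate_possible_snvs(
                m,
                study.cds_sequences[m.transcript_id],
                study.annotations[m.transcript_id],
                study.cds_maps[m.transcript_id],
            )
        )
    snvs = pd.concat(frames, ignore_index=True)
    n0 = len(snvs)
    snvs = snvs.merge(rates, on=["chrom", "pos", "ref", "alt"], how="inner")
    logger.info("rate join: %d of %d possible SNVs have a raw rate", len(snvs), n0)
    if cohort is not None:
        obs = cohort[["chrom", "pos", "ref", "alt", "allele_count"]].drop_duplicates(
            ["chrom", "pos", "ref", "alt"]
        )
        snvs = snvs.merge(obs, on=["chrom", "pos", "ref", "alt"], how="left")
        snvs["observed"] = snvs["allele_count"].notna() & (snvs["allele_count"] >= 1)
        snvs["allele_count"] = snvs["allele_count"].fillna(0).astype(int)
    if depths is not None:
        snvs = snvs.merge(depths, on=["chrom", "pos"], how="left")
        snvs["median_depth"] = snvs["median_depth"].fillna(10**6)
    return snvs


def run_constraint_pipeline(
    snvs: pd.DataFrame,
    *,
    depth_threshold: int = mutation_model.DEFAULT_DEPTH_THRESHOLD,
    isotonic: bool = True,
    **constraint_kwargs,
) -> tuple[mutation_model.CalibrationCurve, pd.DataFrame, pd.DataFrame]:
    """Calibrate on synonymous background, then test regional constraint.

    Returns (calibration curve, per-region expected counts, constraint
    results).
    """
    background = snvs[snvs["consequence"] == consequences.SYNONYMOUS]
    curve = mutation_model.calibrate_scaled_rates(
        background["raw_rate"].to_numpy(),
        background["observed"].to_numpy(),
        isotonic=isotonic,
    )
    snvs = mutation_model.attach_scaled_rates(snvs, curve)
    counts = mutation_model.expected_counts(snvs, depth_threshold=depth_threshold)
    results = constraint.compute_constraint(
        snvs, depth_threshold=depth_threshold, **constraint_kwargs
    )
    return curve, counts, results


def write_run_config(path: str | Path, **config) -> None:
    """Serialise the effective run configuration next to the outputs."""
    Path(path).write_text(json.dumps(config, indent=2, sort_keys=True, default=str) + "\n")
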