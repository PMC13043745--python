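"""De novo variant (DNV) analyses over regional constraint annotations.

Trio-derived DNVs are filtered on population and cohort allele counts,
deduplicated across overlapping cohorts, and then used for three
analyses: relative enrichment of DNVs in constrained versus unconstrained
regions (normalised by the number of unique SNVs expected under the
mutational model, with percentile-bootstrap intervals), diagnostic odds
ratios for carriers of qualifying DNVs, and a screen for candidate
disease genes with clusters of truncating DNVs in constrained regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from nmdconstraint.constraint import CONSTRAINED, UNCONSTRAINED

logger = logging.getLogger(__name__)

FRAMESHIFT = "frameshift"
DNV_CONSEQUENCES = ("synonymous", "missense", "nonsense", FRAMESHIFT)
PTV = "ptv"  # nonsense + frameshift pooled
SOLVED_VALUES = {"yes", "partially"}

VARIANT_KEY = ["chrom", "pos", "ref", "alt"]


@dataclass
class DnvFilterThresholds:
    """Rarity and consequence filters applied to DNV records."""

    population_ac_max: int = 1
    population_af_max: float = 1e-4
    cohort_ac_max: int = 5
    consequences: tuple[str, ...] = DNV_CONSEQUENCES


def filter_dnvs(records: pd.DataFrame, thresholds: DnvFilterThresholds | None = None) -> pd.DataFrame:
    """Drop DNVs failing rarity thresholds or outside the four classes.

    Missing annotation values are treated as passing (and logged), since
    absence from a population database is itself evidence of rarity.
    """
    t = thresholds or DnvFilterThresholds()
    df = records.copy()
    n_in = len(df)
    keep = df["consequence"].isin(t.consequences)

    def _le(col: str, bound: float) -> pd.Series:
        if col not in df:
            logger.info("filter_dnvs: column %s absent; all records pass", col)
            return pd.Series(True, index=df.index)
        vals = df[col]
        missing = vals.isna()
        if missing.any():
            logger.info("filter_dnvs: %d records missing %s treated as passing", missing.sum(), col)
        return missing | (vals <= bound)

    keep &= _le("population_ac", t.population_ac_max)
    keep &= _le("population_af", t.population_af_max)
    keep &= _le("cohort_ac", t.cohort_ac_max)
    out = df[keep].reset_index(drop=True)
    logger.info("filter_dnvs: %d in, %d out", n_in, len(out))
    return out


def dedup_across_cohorts(records: pd.DataFrame, cohort_priority: list[str]) -> pd.DataFrame:
    """Remove cross-cohort duplicate variants, keeping the higher-priority cohort.

    A variant key (chrom, pos, ref, alt) seen in a higher-priority cohort
    is dropped from every lower-priority cohort. Duplicates *within* one
    cohort (different probands) are kept: they are distinct de novo events.
    """
    df = records.copy()
    seen: set[tuple] = set()
    keep_parts = []
    for cohort in cohort_priority:
        sub = df[df["cohort"] == cohort]
        keys = list(map(tuple, sub[VARIANT_KEY].itertuples(index=False, name=None)))
        mask = [k not in seen for k in keys]
        dropped = len(mask) - sum(mask)
        if dropped:
            logger.info("dedup: dropped %d DNVs from cohort %s", dropped, cohort)
        keep_parts.append(sub[mask])
        seen.update(keys)
    unknown = df[~df["cohort"].isin(cohort_priority)]
    if len(unknown):
        raise ValueError(f"cohorts {sorted(unknown['cohort'].unique())} not in priority list")
    return pd.concat(keep_parts, ignore_index=True)


def dnv_class(consequence: pd.Series) -> pd.Series:
    """Collapse nonsense + frameshift into one protein-truncating class."""
    return consequence.where(~consequence.isin(["nonsense", FRAMESHIFT]), PTV)


@dataclass
class EnrichmentResult:
    category: str
    dnv_constrained: int
    dnv_unconstrained: int
    expected_constrained: float
    expected_unconstrained: float
    relative_enrichment: float
    ci_lo: float = float("nan")
    ci_hi: float = float("nan")
    bootstrap_p: float = float("nan")
    significant_bonferroni: bool = False


def _ratio(d_con, d_unc, e_con, e_unc) -> float:
    if d_unc == 0 or e_con <= 0 or e_unc <= 0:
        return float("nan")
    return (d_con / e_con) / (d_unc / e_unc)


def regional_enrichment(
    dnvs: pd.DataFrame,
    expected: pd.DataFrame,
    *,
    by_region: bool = False,
    n_boot: int = 10_000,
    seed: int = 0,
    family_size: int | None = None,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Relative enrichment of DNVs in constrained vs unconstrained regions.

    ``dnvs`` needs consequence, region, constraint (and proband_id)
    columns; records in indeterminate or unannotated regions are ignored.
    ``expected`` gives the number of unique SNVs expected under the
    mutational model per (class, region, constraint) with columns
    [class, region, constraint, n_expected]; region "all" aggregates.
    Nonsense and frameshift DNVs are pooled into the ``ptv`` class and
    adjusted by the *nonsense* expectation.

    Enrichment = (DNV_constrained / E_constrained) /
    (DNV_unconstrained / E_unconstrained). Percentile-bootstrap CI and
    two-sided p resample individual DNV records with replacement.
    """
    rng = np.random.default_rng(seed)
    df = dnvs[dnvs["constraint"].isin([CONSTRAINED, UNCONSTRAINED])].copy()
    df["class"] = dnv_class(df["consequence"])
    exp = expected.copy()

    categories: list[tuple[str, str, str]] = []  # (label, class, region)
    for cls in (PTV, "missense", "synonymous"):
        if by_region:
            for region in sorted(df.loc[df["class"] == cls, "region"].dropna().unique()):
                categories.append((f"{cls}:{region}", cls, region))
        else:
            categories.append((cls, cls, "all"))

    if family_size is None:
        family_size = len(categories)
    threshold = alpha / max(family_size, 1)

    results = []
    for label, cls, region in categories:
        sub = df[df["class"] == cls]
        if region != "all":
            sub = sub[sub["region"] == region]
        e = exp[(exp["class"] == cls) & (exp["region"] == region)]
        e_con = float(e.loc[e["constraint"] == CONSTRAINED, "n_expected"].sum())
        e_unc = float(e.loc[e["constraint"] == UNCONSTRAINED, "n_expected"].sum())
        arm = (sub["constraint"] == CONSTRAINED).to_numpy()
        d_con, d_unc = int(arm.sum()), int((~arm).sum())
        point = _ratio(d_con, d_unc, e_con, e_unc)
        res = EnrichmentResult(label, d_con, d_unc, e_con, e_unc, point)
        if np.isfinite(point) and len(arm) and n_boot > 0:
            draws = rng.integers(0, len(arm), size=(n_boot, len(arm)))
            boot_con = arm[draws].sum(axis=1)
            boot_unc = len(arm) - boot_con
            with np.errstate(divide="ignore", invalid="ignore"):
                boot = (boot_con / e_con) / (boot_unc / e_unc)
            boot = boot[np.isfinite(boot)]
            if len(boot):
                res.ci_lo = float(np.quantile(boot, alpha / 2))
                res.ci_hi = float(np.quantile(boot, 1 - alpha / 2))
                lo_frac = float(np.mean(boot <= 1.0))
                hi_frac = float(np.mean(boot >= 1.0))
                res.bootstrap_p = float(min(1.0, 2.0 * min(lo_frac, hi_frac)))
                res.significant_bonferroni = res.bootstrap_p < threshold
        results.append(res)
    return results


def expected_by_constraint(
    region_counts: pd.DataFrame, constraint_results: pd.DataFrame
) -> pd.DataFrame:
    """Expected unique SNVs per (class, region, constraint arm).

    Joins the per-region classification onto the expected-count table and
    aggregates; the nonsense expectation is relabelled ``ptv`` so it can
    normalise the pooled nonsense+frameshift DNV class. Region "all" rows
    aggregate over regions.
    """
    cls_map = constraint_results[["transcript_id", "region", "classification"]]
    merged = region_counts.merge(cls_map, on=["transcript_id", "region"], how="inner")
    merged = merged[merged["classification"].isin([CONSTRAINED, UNCONSTRAINED])]
    merged["class"] = merged["consequence"].replace({"nonsense": PTV})
    per_region = (
        merged.groupby(["class", "region", "classification"], observed=True)["n_expected"]
        .sum()
        .reset_index()
        .rename(columns={"classification": "constraint"})
    )
    overall = (
        per_region.groupby(["class", "constraint"], observed=True)["n_expected"]
        .sum()
        .reset_index()
    )
    overall["region"] = "all"
    return pd.concat([per_region, overall], ignore_index=True)


@dataclass
class OddsResult:
    category: str
    table: tuple[tuple[float, float], tuple[float, float]]
    odds_ratio: float
    ci_lo: float
    ci_hi: float
    p: float
    significant_bonferroni: bool
    haldane_corrected: bool = False


def diagnostic_odds(
    carriers: dict[str, set],
    outcomes: pd.DataFrame,
    *,
    family_size: int = 14,
    alpha: float = 0.05,
) -> list[OddsResult]:
    """Odds of a solved case for carriers of qualifying DNVs per category.

    ``outcomes`` has proband_id and case_solved columns; 'yes' and
    'partially' count as solved, everything else (including absent) as
    unsolved. Each 2x2 table is carrier status x solved status; the OR
    uses the Woolf log-SE normal interval and a two-sided Z test on the
    log odds ratio, with Haldane–Anscombe 0.5 correction on zero cells.
    """
    solved = outcomes.set_index("proband_id")["case_solved"].isin(SOLVED_VALUES)
    threshold = alpha / max(family_size, 1)
    results = []
    for category in sorted(carriers):
        carrier_ids = carriers[category]
        is_carrier = solved.index.isin(carrier_ids)
        a = float((solved & is_carrier).sum())  # carrier, solved
        b = float((~solved & is_carrier).sum())  # carrier, unsolved
        c = float((solved & ~is_carrier).sum())
        d = float((~solved & ~is_carrier).sum())
        corrected = False
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            corrected = True
        or_ = (a * d) / (b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = np.log(or_) / se
        p = float(2 * stats.norm.sf(abs(z)))
        results.append(
            OddsResult(
                category=category,
                table=((a, b), (c, d)),
                odds_ratio=float(or_),
                ci_lo=float(np.exp(np.log(or_) - 1.96 * se)),
                ci_hi=float(np.exp(np.log(or_) + 1.96 * se)),
                p=p,
                significant_bonferroni=p < threshold,
                haldane_corrected=corrected,
            )
        )
    return results


def ptv_carrier_sets(dnvs: pd.DataFrame) -> dict[str, set]:
    """Proband sets carrying >=1 truncating DNV, per constraint arm and region."""
    ptv = dnvs[dnvs["consequence"].isin(["nonsense", FRAMESHIFT])]
    out: dict[str, set] = {}
    for arm in (CONSTRAINED, UNCONSTRAINED):
        sub = ptv[ptv["constraint"] == arm]
        out[f"{arm}:transcript"] = set(sub["proband_id"])
        for region, grp in sub.groupby("region", observed=True):
            out[f"{arm}:{region}"] = set(grp["proband_id"])
    return out


def candidate_gene_screen(
    dnvs: pd.DataFrame,
    constraint_results: pd.DataFrame,
    known_gene_lists: dict[str, set] | None = None,
    *,
    min_dnvs: int = 3,
    oe_threshold: float = 0.3,
    max_observed_nonsense: int = 20,
) -> pd.DataFrame:
    """Screen for candidate disease genes.

    Keeps genes with >= ``min_dnvs`` truncating DNVs inside one
    constrained region whose nonsense O/E is below ``oe_threshold`` and
    whose reference-cohort observed nonsense count is below
    ``max_observed_nonsense``, excluding genes on any supplied curated
    disease-gene list.
    """
    known: set = set()
    for name, genes in (known_gene_lists or {}).items():
        logger.info("candidate screen: excluding %d genes from list %s", len(genes), name)
        known |= set(genes)

    ptv = dnvs[
        dnvs["consequence"].isin(["nonsense", FRAMESHIFT])
        & (dnvs["constraint"] == CONSTRAINED)
    ]
    counts = (
        ptv.groupby(["gene_id", "transcript_id", "region"], observed=True)
        .size()
        .rename("n_dnvs")
        .reset_index()
    )
    merged = counts.merge(
        constraint_results[
            ["transcript_id", "region", "oe", "n_observed", "classification"]
        ],
        on=["transcript_id", "region"],
        how="left",
    )
    hits = merged[
        (merged["n_dnvs"] >= min_dnvs)
        & (merged["classification"] == CONSTRAINED)
        & (merged["oe"] < oe_threshold)
        & (merged["n_observed"] < max_observed_nonsense)
        & ~merged["gene_id"].isin(known)
    ]
    return hits.reset_index(drop=True)
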