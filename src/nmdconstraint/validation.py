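"""Seeded simulation studies that characterise the method's calibration.

Each function simulates data under a known truth with the package's own
generators and measures how well the pipeline recovers it: type-I error
of the constraint classifier under neutrality, power under strong
selection, O/E estimation bias, MAPS calibration and monotonicity, de
novo enrichment recovery, and diagnostic odds-ratio recovery. They are
shared by the test suite and the acceptance script so both report the
same quantities at the same problem sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from nmdconstraint import maps_stats
from nmdconstraint.consequences import NONSENSE, SYNONYMOUS
from nmdconstraint.constraint import CONSTRAINED, compute_constraint
from nmdconstraint.dnv_analysis import diagnostic_odds, regional_enrichment
from nmdconstraint.mutation_model import calibrate_scaled_rates, expected_counts
from nmdconstraint.nmd_regions import FINAL_LABELS
from nmdconstraint.synthetic_data import SimConfig, simulate_cohort, simulate_transcriptome


def simulate_depletion_regions(
    seed: int,
    n_regions: int,
    n_nonsense: int,
    oe_true: float,
    *,
    n_synonymous: int | None = None,
    rate_log_mean: float = np.log(0.08),
    rate_log_sd: float = 0.5,
) -> pd.DataFrame:
    """Region-level SNV table: Bernoulli observation at known true O/E.

    Each simulated region carries ``n_nonsense`` nonsense and
    ``n_synonymous`` synonymous sites with log-normal scaled rates
    (clipped to [0, 1]); nonsense sites are observed with probability
    rate * oe_true, synonymous sites neutrally.
    """
    rng = np.random.default_rng(seed)
    if n_synonymous is None:
        n_synonymous = n_nonsense
    frames = []
    for cons, n_sites, oe in ((NONSENSE, n_nonsense, oe_true), (SYNONYMOUS, n_synonymous, 1.0)):
        total = n_regions * n_sites
        rates = np.clip(np.exp(rng.normal(rate_log_mean, rate_log_sd, total)), 0.0, 1.0)
        obs = rng.random(total) < rates * oe
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": np.repeat([f"R{i:05d}" for i in range(n_regions)], n_sites),
                    "region": "nmd_target",
                    "consequence": cons,
                    "scaled_rate": rates,
                    "observed": obs,
                    "median_depth": 30,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def neutral_false_positive_rate(
    seed: int, *, n_regions: int = 1000, n_nonsense: int = 150
) -> float:
    """Fraction of neutral regions called constrained at FDR 0.05.

    Expected nonsense count per region is ~13 (>= 10), so the classifier
    has data to act on; under the null the fraction should be near zero.
    """
    snvs = simulate_depletion_regions(seed, n_regions, n_nonsense, oe_true=1.0)
    res = compute_constraint(snvs, include_full_cds=False)
    return float((res["classification"] == CONSTRAINED).mean())


def constraint_power(
    seed: int, *, n_regions: int = 300, n_nonsense: int = 260, oe_true: float = 0.2
) -> float:
    """Fraction of truly depleted regions (true O/E) called constrained.

    n_nonsense = 260 at mean rate ~0.09 gives expected counts >= 20.
    """
    snvs = simulate_depletion_regions(seed, n_regions, n_nonsense, oe_true=oe_true)
    res = compute_constraint(snvs, include_full_cds=False)
    return float((res["classification"] == CONSTRAINED).mean())


def oe_recovery(
    seed: int, *, n_regions: int = 500, n_nonsense: int = 620, oe_true: float = 0.5
) -> float:
    """Mean estimated O/E over regions simulated at a known true O/E.

    n_nonsense = 620 gives expected counts >= 50 per region.
    """
    snvs = simulate_depletion_regions(seed, n_regions, n_nonsense, oe_true=oe_true)
    res = compute_constraint(snvs, include_full_cds=False)
    return float(res["oe"].mean())


# ---------------------------------------------------------------------------
# MAPS calibration on the full synthetic cohort


def _maps_inputs(seed: int, s_nonsense: float, n_transcripts: int = 150):
    cfg = SimConfig(seed=seed, n_transcripts=n_transcripts)
    study = simulate_transcriptome(cfg)
    if s_nonsense > 0:
        cfg_sel = SimConfig(
            seed=seed,
            n_transcripts=n_transcripts,
            s_region={r: s_nonsense for r in FINAL_LABELS},
        )
        cohort = simulate_cohort(study, config=cfg_sel)
    else:
        cohort = simulate_cohort(study)
    background = cohort[cohort["consequence"] == SYNONYMOUS]
    curve = calibrate_scaled_rates(
        background["raw_rate"].to_numpy(), background["observed"].to_numpy()
    )
    cohort = cohort.assign(scaled_rate=curve.lookup(cohort["raw_rate"].to_numpy()))
    return cohort


def maps_neutral_holdout(seed: int, *, n_transcripts: int = 150) -> float:
    """MAPS of a held-out half of the neutral synonymous background.

    The PS model is fitted on one half of the observed synonymous
    variants (weights from the full possible set) and evaluated on the
    other half; under neutrality the result should be ~0.
    """
    cohort = _maps_inputs(seed, s_nonsense=0.0, n_transcripts=n_transcripts)
    syn = cohort[cohort["consequence"] == SYNONYMOUS]
    syn_obs = syn[syn["observed"]].reset_index(drop=True)
    train = syn_obs.iloc[::2]
    test = syn_obs.iloc[1::2]
    contexts = maps_stats.singleton_contexts(train, possible=syn)
    model = maps_stats.fit_ps_model(contexts)
    return maps_stats.compute_maps(test, model, label="held_out_synonymous").maps


def maps_under_selection(seed: int, s_values=(0.0, 0.3, 0.6, 0.9)) -> list[float]:
    """Nonsense MAPS at increasing selection strength (same transcriptome)."""
    out = []
    for s in s_values:
        cohort = _maps_inputs(seed, s_nonsense=float(s))
        syn = cohort[cohort["consequence"] == SYNONYMOUS]
        contexts = maps_stats.singleton_contexts(syn[syn["observed"]], possible=syn)
        model = maps_stats.fit_ps_model(contexts)
        non_obs = cohort[(cohort["consequence"] == NONSENSE) & cohort["observed"]]
        out.append(maps_stats.compute_maps(non_obs, model, label=f"nonsense_s{s}").maps)
    return out


# ---------------------------------------------------------------------------
# DNV enrichment and diagnostic odds recovery


def simulate_dnv_arm_counts(
    rng: np.random.Generator,
    *,
    enrichment: float,
    expected_constrained: float = 100.0,
    expected_unconstrained: float = 200.0,
    nu: float = 2.0,
) -> pd.DataFrame:
    """Poisson DNV records over two constraint arms at known enrichment."""
    n_con = rng.poisson(nu * expected_constrained * enrichment)
    n_unc = rng.poisson(nu * expected_unconstrained)
    return pd.DataFrame(
        {
            "consequence": "nonsense",
            "region": "nmd_target",
            "constraint": ["constrained"] * n_con + ["unconstrained"] * n_unc,
            "proband_id": "P0",
        }
    )


def dnv_enrichment_replicates(
    seed: int,
    *,
    enrichment: float = 5.0,
    n_replicates: int = 100,
    n_boot: int = 2000,
    expected_constrained: float = 100.0,
    expected_unconstrained: float = 200.0,
) -> pd.DataFrame:
    """Replicate enrichment estimates with bootstrap CIs at known truth.

    With nu = 2 the arms hold ~1000 and ~400 DNVs (>= 200 per arm).
    Returns one row per replicate: point, ci_lo, ci_hi, covered.
    """
    rng = np.random.default_rng(seed)
    expected = pd.DataFrame(
        {
            "class": ["ptv", "ptv"],
            "region": ["all", "all"],
            "constraint": ["constrained", "unconstrained"],
            "n_expected": [expected_constrained, expected_unconstrained],
        }
    )
    rows = []
    for rep in range(n_replicates):
        dnvs = simulate_dnv_arm_counts(
            rng,
            enrichment=enrichment,
            expected_constrained=expected_constrained,
            expected_unconstrained=expected_unconstrained,
        )
        res = regional_enrichment(
            dnvs, expected, n_boot=n_boot, seed=int(rng.integers(0, 2**31 - 1))
        )
        ptv = next(r for r in res if r.category == "ptv")
        rows.append(
            {
                "replicate": rep,
                "point": ptv.relative_enrichment,
                "ci_lo": ptv.ci_lo,
                "ci_hi": ptv.ci_hi,
                "covered": bool(ptv.ci_lo <= enrichment <= ptv.ci_hi),
            }
        )
    return pd.DataFrame(rows)


def null_enrichment_mean(seed: int, *, n_replicates: int = 200) -> float:
    """Mean enrichment point estimate under the null generator (e = 1)."""
    rng = np.random.default_rng(seed)
    expected = pd.DataFrame(
        {
            "class": ["ptv", "ptv"],
            "region": ["all", "all"],
            "constraint": ["constrained", "unconstrained"],
            "n_expected": [100.0, 200.0],
        }
    )
    points = []
    for _ in range(n_replicates):
        dnvs = simulate_dnv_arm_counts(rng, enrichment=1.0)
        res = regional_enrichment(dnvs, expected, n_boot=0, seed=0)
        points.append(next(r for r in res if r.category == "ptv").relative_enrichment)
    return float(np.nanmean(points))


def diagnostic_or_recovery(
    seed: int,
    *,
    or_true: float = 4.0,
    n_trios: int = 5000,
    carrier_fraction: float = 0.08,
    solved_baseline: float = 0.3,
) -> float:
    """Recovered odds ratio from a simulated logistic outcome model."""
    rng = np.random.default_rng(seed)
    carrier = rng.random(n_trios) < carrier_fraction
    base_odds = solved_baseline / (1 - solved_baseline)
    odds = np.where(carrier, base_odds * or_true, base_odds)
    solved = rng.random(n_trios) < odds / (1 + odds)
    probands = np.array([f"P{i:06d}" for i in range(n_trios)])
    outcomes = pd.DataFrame(
        {"proband_id": probands, "case_solved": np.where(solved, "yes", "no")}
    )
    carriers = {"constrained:transcript": set(probands[carrier])}
    res = diagnostic_odds(carriers, outcomes, family_size=1)
    return res[0].odds_ratio


# ---------------------------------------------------------------------------
# End-to-end O/E recovery through the full synthetic pipeline


def end_to_end_oe_recovery(
    seed: int,
    *,
    n_transcripts: int = 300,
    s_region: dict[str, float] | None = None,
) -> dict[str, float]:
    """Per-region pooled nonsense O/E through the full pipeline.

    Simulates a transcriptome and cohort with region-specific selection,
    calibrates scaled rates on the synonymous background, and returns the
    pooled observed/expected nonsense ratio per region; the truth is
    1 - s_region.
    """
    if s_region is None:
        s_region = {
            "nmd_target": 0.7,
            "long_exon": 0.8,
            "distal": 0.9,
            "start_proximal": 0.5,
        }
    cfg = SimConfig(seed=seed, n_transcripts=n_transcripts, s_region=s_region)
    study = simulate_transcriptome(cfg)
    cohort = simulate_cohort(study)
    background = cohort[cohort["consequence"] == SYNONYMOUS]
    curve = calibrate_scaled_rates(
        background["raw_rate"].to_numpy(), background["observed"].to_numpy()
    )
    cohort = cohort.assign(scaled_rate=curve.lookup(cohort["raw_rate"].to_numpy()))
    counts = expected_counts(cohort, include_full_cds=False)
    non = counts[counts["consequence"] == NONSENSE]
    pooled = non.groupby("region", observed=True)[["n_observed", "n_expected"]].sum()
    return {r: float(row["n_observed"] / row["n_expected"]) for r, row in pooled.iterrows()}
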