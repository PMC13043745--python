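"""Mutation-rate calibration and expected variant counts.

Raw per-SNV mutation rates (arbitrary positive units, e.g. a Roulette-like
per-generation rate) are scaled to the probability that the site is
observed segregating in the cohort under neutrality, by measuring the
proportion of *neutral background* sites (high-quality synonymous SNVs)
observed at each raw-rate value. The scaled rates then give expected
variant counts per transcript/region as a sum of per-site observation
probabilities.

Sites with median sequencing depth below threshold are removed from both
the possible and the observed tallies, so poor coverage cannot masquerade
as depletion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

logger = logging.getLogger(__name__)

FULL_CDS = "full_cds"
DEFAULT_DEPTH_THRESHOLD = 20
MAX_DISTINCT_RATE_VALUES = 256
N_QUANTILE_BINS = 100


@dataclass
class CalibrationCurve:
    """Lookup from raw mutation rate to neutral observation probability.

    ``bin_rates`` are representative raw-rate values (bin means), sorted
    ascending; ``scaled`` the per-bin proportion of background sites
    observed (after optional isotonic smoothing); ``n_sites`` the bin
    occupancy used as smoothing weight.
    """

    bin_rates: np.ndarray
    scaled: np.ndarray
    n_sites: np.ndarray
    monotone: bool

    def __post_init__(self) -> None:
        if np.any((self.scaled < 0) | (self.scaled > 1)):
            raise ValueError("scaled rates must lie in [0, 1]")
        if self.monotone and np.any(np.diff(self.scaled) < -1e-12):
            raise ValueError("curve flagged monotone but scaled rates decrease")

    def lookup(self, raw_rates) -> np.ndarray:
        """Scaled rate for each raw rate, by nearest calibration bin."""
        raw = np.asarray(raw_rates, dtype=float)
        edges = (self.bin_rates[1:] + self.bin_rates[:-1]) / 2
        idx = np.searchsorted(edges, raw)
        return self.scaled[idx]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"raw_rate": self.bin_rates, "scaled_rate": self.scaled, "n_sites": self.n_sites}
        )


def calibrate_scaled_rates(
    raw_rates,
    observed_flags,
    *,
    isotonic: bool = True,
    max_distinct: int = MAX_DISTINCT_RATE_VALUES,
    n_quantile_bins: int = N_QUANTILE_BINS,
) -> CalibrationCurve:
    """Fit the raw-rate -> observation-probability curve on background sites.

    Bins by distinct raw-rate value when there are at most ``max_distinct``
    distinct values (mutation-rate models typically emit a small discrete
    set), otherwise by ``n_quantile_bins`` equal-count quantile bins.
    Isotonic (pool-adjacent-violators) smoothing, weighted by bin occupancy,
    enforces that observation probability is non-decreasing in mutability.
    """
    raw = np.asarray(raw_rates, dtype=float)
    obs = np.asarray(observed_flags, dtype=bool)
    if raw.size == 0:
        raise ValueError("empty background set")
    if raw.shape != obs.shape:
        raise ValueError("raw_rates and observed_flags differ in length")
    if np.any(raw <= 0):
        raise ValueError("raw rates must be positive")

    values = np.unique(raw)
    if len(values) <= max_distinct:
        key = np.searchsorted(values, raw)
        n_bins = len(values)
    else:
        quantiles = np.quantile(raw, np.linspace(0, 1, n_quantile_bins + 1)[1:-1])
        key = np.searchsorted(quantiles, raw)
        n_bins = n_quantile_bins

    n_sites = np.bincount(key, minlength=n_bins)
    n_obs = np.bincount(key, weights=obs.astype(float), minlength=n_bins)
    rate_sum = np.bincount(key, weights=raw, minlength=n_bins)
    occupied = n_sites > 0
    if not occupied.all():
        logger.warning("%d empty calibration bins excluded", int((~occupied).sum()))
    n_sites = n_sites[occupied]
    prop = n_obs[occupied] / n_sites
    bin_rates = rate_sum[occupied] / n_sites

    order = np.argsort(bin_rates)
    bin_rates, prop, n_sites = bin_rates[order], prop[order], n_sites[order]

    if isotonic and len(bin_rates) > 1:
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True)
        scaled = iso.fit_transform(bin_rates, prop, sample_weight=n_sites)
    else:
        scaled = np.clip(prop, 0.0, 1.0)
    return CalibrationCurve(bin_rates, np.asarray(scaled, float), n_sites, monotone=isotonic)


def attach_scaled_rates(snvs: pd.DataFrame, curve: CalibrationCurve) -> pd.DataFrame:
    """Add a ``scaled_rate`` column looked up from ``raw_rate``."""
    if "raw_rate" not in snvs:
        raise ValueError("SNV table lacks a raw_rate column")
    out = snvs.copy()
    out["scaled_rate"] = curve.lookup(out["raw_rate"].to_numpy())
    return out


def expected_counts(
    snvs: pd.DataFrame,
    *,
    depth_threshold: int | None = DEFAULT_DEPTH_THRESHOLD,
    include_full_cds: bool = True,
) -> pd.DataFrame:
    """Possible/observed/expected counts per transcript x region x consequence.

    ``snvs`` must carry ``scaled_rate`` (error if absent or missing values),
    an ``observed`` flag, and — when ``depth_threshold`` is not None — a
    ``median_depth`` column. Sites below the depth threshold are removed
    from possible and observed counts alike. A whole-transcript group
    (region = ``full_cds``) is appended unless disabled.

    Returns columns: transcript_id, region, consequence, n_possible,
    n_observed, n_expected, mean_scaled_rate.
    """
    if "scaled_rate" not in snvs or snvs["scaled_rate"].isna().any():
        raise ValueError("every SNV needs a scaled_rate before expected counts")
    df = snvs
    if depth_threshold is not None:
        if "median_depth" not in df:
            raise ValueError("depth filtering requested but median_depth column absent")
        df = df[df["median_depth"] >= depth_threshold]

    def _group(frame: pd.DataFrame, region_key) -> pd.DataFrame:
        g = frame.groupby(["transcript_id", region_key, "consequence"], observed=True)
        out = g.agg(
            n_possible=("scaled_rate", "size"),
            n_observed=("observed", "sum"),
            n_expected=("scaled_rate", "sum"),
        ).reset_index()
        out = out.rename(columns={region_key if isinstance(region_key, str) else "region": "region"})
        out["mean_scaled_rate"] = out["n_expected"] / out["n_possible"]
        return out

    parts = [_group(df, "region")]
    if include_full_cds:
        whole = df.copy()
        whole["region"] = FULL_CDS
        parts.append(_group(whole, "region"))
    out = pd.concat(parts, ignore_index=True)
    out["n_observed"] = out["n_observed"].astype(int)
    return out.sort_values(
        ["transcript_id", "region", "consequence"], kind="mergesort", ignore_index=True
    )


def read_rate_table(path: str) -> pd.DataFrame:
    """Read a per-SNV rate TSV (chrom, pos, ref, alt, raw_rate)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "raw_rate"}
    if missing := required - set(df.columns):
        raise ValueError(f"rate table {path} lacks columns {sorted(missing)}")
    return df


def read_depth_table(path: str) -> pd.DataFrame:
    """Read a per-site depth TSV (chrom, pos, median_depth)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "median_depth"}
    if missing := required - set(df.columns):
        raise ValueError(f"depth table {path} lacks columns {sorted(missing)}")
    return df
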