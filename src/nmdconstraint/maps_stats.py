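"""Mutability-adjusted proportion of singletons (MAPS).

More mutable sites segregate at higher frequencies, so their raw
proportion of singletons (PS, allele count == 1) is lower. MAPS removes
this mutability effect: a weighted least squares model of PS against the
scaled mutation rate is fitted on synonymous variants (one point per
distinct rate value, weighted by the number of possible variants at that
rate), the model predicts the expected PS for any variant class, and
MAPS = observed PS - expected PS. Positive MAPS indicates an excess of
rare variants, i.e. purifying selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class MapsModel:
    """Linear WLS fit of the proportion of singletons on the scaled rate."""

    intercept: float
    slope: float
    n_contexts: int
    weighted_rss: float

    def predict(self, scaled_rates) -> np.ndarray:
        """Predicted PS, clipped to [0, 1]."""
        r = np.asarray(scaled_rates, dtype=float)
        return np.clip(self.intercept + self.slope * r, 0.0, 1.0)


@dataclass
class MapsResult:
    label: str
    n_observed: int
    ps_observed: float
    ps_expected: float
    maps: float
    ci_halfwidth: float


def singleton_contexts(variants: pd.DataFrame, possible: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-rate-value PS table from observed variants.

    ``variants`` needs scaled_rate and allele_count columns (observed
    variants only). ``possible`` — the full possible-SNV table with
    scaled_rate — supplies the n_possible weight per context; when absent,
    the number of observed variants is used as weight.
    """
    obs = variants.groupby("scaled_rate", observed=True).agg(
        n_observed=("allele_count", "size"),
        n_singletons=("allele_count", lambda ac: int((ac == 1).sum())),
    )
    obs["ps_observed"] = obs["n_singletons"] / obs["n_observed"]
    if possible is not None:
        w = possible.groupby("scaled_rate", observed=True).size().rename("n_possible")
        obs = obs.join(w, how="left")
        obs["n_possible"] = obs["n_possible"].fillna(obs["n_observed"])
    else:
        obs["n_possible"] = obs["n_observed"]
    return obs.reset_index()


def fit_ps_model(contexts: pd.DataFrame) -> MapsModel:
    """Weighted least squares of ps_observed on scaled_rate.

    ``contexts`` needs scaled_rate, ps_observed and n_possible columns
    (as produced by :func:`singleton_contexts`); at least two distinct
    rate values are required.
    """
    rates = contexts["scaled_rate"].to_numpy(dtype=float)
    if len(np.unique(rates)) < 2:
        raise ValueError("need >= 2 distinct scaled rates to fit the PS model")
    y = contexts["ps_observed"].to_numpy(dtype=float)
    w = contexts["n_possible"].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValueError("context weights must be positive")
    fit = sm.WLS(y, sm.add_constant(rates), weights=w).fit()
    resid = y - fit.fittedvalues
    return MapsModel(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        n_contexts=len(rates),
        weighted_rss=float(np.sum(w * resid**2)),
    )


def compute_maps(class_variants: pd.DataFrame, model: MapsModel, label: str = "") -> MapsResult:
    """MAPS for one variant class (a set of observed variants).

    ps_expected averages the model's clipped predictions over the class's
    observed variants; the CI half-width is the normal-approximation
    binomial standard error on ps_observed times 1.96.
    """
    n = len(class_variants)
    if n == 0:
        raise ValueError(f"class {label!r} has no observed variants; MAPS undefined")
    ac = class_variants["allele_count"].to_numpy()
    ps_obs = float((ac == 1).mean())
    ps_exp = float(model.predict(class_variants["scaled_rate"].to_numpy()).mean())
    se = np.sqrt(ps_obs * (1.0 - ps_obs) / n)
    return MapsResult(
        label=label,
        n_observed=n,
        ps_observed=ps_obs,
        ps_expected=ps_exp,
        maps=ps_obs - ps_exp,
        ci_halfwidth=float(1.96 * se),
    )


def compare_maps(
    results: list[MapsResult],
    *,
    ps_expected_synonymous: float,
    n_tests: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise two-sided Z tests of proportion between variant classes.

    Each class's proportion is first adjusted onto a common scale:
    adjusted PS = maps + expected synonymous PS, i.e. the PS the class
    would show at synonymous mutability. Bonferroni significance is
    flagged at family size ``n_tests`` (default: the number of pairs).
    """
    usable = [r for r in results if r.n_observed > 0]
    for r in results:
        if r.n_observed == 0:
            logger.info("class %s has no observed variants; excluded from comparisons", r.label)
    if len(usable) < 2:
        raise ValueError("need >= 2 classes with observed variants")
    pairs = [(a, b) for i, a in enumerate(usable) for b in usable[i + 1 :]]
    if n_tests is None:
        n_tests = len(pairs)
    threshold = alpha / n_tests
    rows = []
    for a, b in pairs:
        p1 = np.clip(a.maps + ps_expected_synonymous, 0.0, 1.0)
        p2 = np.clip(b.maps + ps_expected_synonymous, 0.0, 1.0)
        n1, n2 = a.n_observed, b.n_observed
        pooled = (p1 * n1 + p2 * n2) / (n1 + n2)
        se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
        z = 0.0 if se == 0 else (p1 - p2) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "class_a": a.label,
                "class_b": b.label,
                "z": float(z),
                "p": float(p),
                "significant_bonferroni": bool(p < threshold),
            }
        )
    return pd.DataFrame(rows)


def maps_table(results: list[MapsResult]) -> pd.DataFrame:
    """TSV-ready MAPS summary."""
    return pd.DataFrame(
        {
            "class": [r.label for r in results],
            "n": [r.n_observed for r in results],
            "ps_obs": [r.ps_observed for r in results],
            "ps_exp": [r.ps_expected for r in results],
            "maps": [r.maps for r in results],
            "ci_lo": [r.maps - r.ci_halfwidth for r in results],
            "ci_hi": [r.maps + r.ci_halfwidth for r in results],
        }
    )
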