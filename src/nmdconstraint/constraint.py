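"""Regional nonsense constraint: depletion tests, O/E, OE95, classification.

The number of variants observed in a region is modelled as a
Poisson-binomial random variable: one trial per possible SNV, with success
probability equal to that SNV's scaled mutation rate (its neutral
observation probability). Depletion is assessed with the one-sided tail
P(X <= observed); an exact truncated dynamic-programming CDF is used up to
``N_EXACT`` trials and a refined (skewness-corrected) normal approximation
with continuity correction beyond.

O/E is observed/expected; OE95 rescales the upper bound of the two-sided
95% binomial confidence interval on the observed *proportion* by
possible/expected. Regions are classified constrained / unconstrained /
indeterminate from the FDR-adjusted nonsense depletion test, a synonymous
depletion veto, and the OE95 threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from nmdconstraint.consequences import NONSENSE, SYNONYMOUS
from nmdconstraint.mutation_model import FULL_CDS, DEFAULT_DEPTH_THRESHOLD

logger = logging.getLogger(__name__)

N_EXACT = 20_000
CONSTRAINED = "constrained"
UNCONSTRAINED = "unconstrained"
INDETERMINATE = "indeterminate"

EXACT_DP = "exact_dp"
NORMAL_APPROX = "normal_approx"


def poisson_binomial_tail(
    probabilities, x_observed: int, *, n_exact: int = N_EXACT
) -> float:
    """One-sided lower tail P(X <= x_observed) of a Poisson-binomial count.

    Exact truncated DP for up to ``n_exact`` trials; refined normal
    approximation (continuity- and skewness-corrected) above.
    """
    p, x = _validate_pb_args(probabilities, x_observed)
    if len(p) <= n_exact:
        return _pb_tail_exact(p, x)
    return _pb_tail_normal(p, x)


def poisson_binomial_method(n_trials: int, *, n_exact: int = N_EXACT) -> str:
    """Which branch :func:`poisson_binomial_tail` uses for ``n_trials``."""
    return EXACT_DP if n_trials <= n_exact else NORMAL_APPROX


def _validate_pb_args(probabilities, x_observed):
    p = np.asarray(probabilities, dtype=float)
    if p.ndim != 1:
        raise ValueError("probabilities must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("probabilities must lie in [0, 1]")
    x = int(x_observed)
    if not 0 <= x <= len(p):
        raise ValueError(f"x_observed {x} outside [0, {len(p)}]")
    return p, x


def _pb_tail_exact(p: np.ndarray, x: int) -> float:
    """Truncated DP: states 0..x plus one absorbing state for counts > x."""
    if x >= len(p):
        return 1.0
    pmf = np.zeros(x + 2)
    pmf[0] = 1.0
    for pi in p:
        absorbed = pmf[x + 1] + pmf[x] * pi
        pmf[1 : x + 1] = pmf[1 : x + 1] * (1.0 - pi) + pmf[:x] * pi
        pmf[0] *= 1.0 - pi
        pmf[x + 1] = absorbed
    return float(min(1.0, pmf[: x + 1].sum()))


def _pb_tail_normal(p: np.ndarray, x: int) -> float:
    """Refined normal approximation with continuity correction.

    Adds the first Edgeworth (skewness) term to the continuity-corrected
    normal CDF; accurate to a few 1e-3 at the exact/approximate boundary.
    """
    mu = p.sum()
    var = np.sum(p * (1.0 - p))
    if var <= 0:  # degenerate: all probabilities 0 or 1
        return 1.0 if x >= round(mu) else 0.0
    sigma = np.sqrt(var)
    gamma = np.sum(p * (1.0 - p) * (1.0 - 2.0 * p)) / sigma**3
    z = (x + 0.5 - mu) / sigma
    val = stats.norm.cdf(z) + gamma * (1.0 - z * z) * stats.norm.pdf(z) / 6.0
    return float(np.clip(val, 0.0, 1.0))


def oe_and_oe95(
    n_observed: int,
    n_possible: int,
    n_expected: float,
    *,
    alpha: float = 0.05,
    ci_method: str = "clopper-pearson",
) -> tuple[float, float]:
    """Observed/expected ratio and its OE95 upper bound.

    OE95 = (upper bound of the two-sided ``1 - alpha`` binomial CI on the
    proportion observed) x n_possible / n_expected. Default interval is
    Clopper–Pearson (exact); ``ci_method="wilson"`` switches to Wilson.
    """
    if n_possible <= 0:
        raise ValueError("n_possible must be positive")
    if not 0 <= n_observed <= n_possible:
        raise ValueError("n_observed outside [0, n_possible]")
    if n_expected <= 0:
        return (float("nan"), float("nan"))
    method = {"clopper-pearson": "beta", "wilson": "wilson"}[ci_method]
    _, upper = proportion_confint(n_observed, n_possible, alpha=alpha, method=method)
    oe = n_observed / n_expected
    oe95 = upper * n_possible / n_expected
    return (float(oe), float(oe95))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_regions(
    results: pd.DataFrame,
    *,
    fdr_alpha: float = 0.05,
    oe95_threshold: float = 0.6,
) -> pd.DataFrame:
    """Attach constrained/unconstrained/indeterminate labels.

    constrained:   q_fdr < alpha AND syn_p >= 0.05 AND oe95 < threshold
    unconstrained: p_depletion >= 0.05 AND n_observed >= 1
    otherwise indeterminate. Rows with missing syn_p cannot be called
    constrained and fall through to the other rules (warned).
    """
    out = results.copy()
    syn_p = out["syn_p"]
    if syn_p.isna().any():
        logger.warning(
            "%d regions lack a synonymous depletion p value; "
            "they cannot be classified constrained",
            int(syn_p.isna().sum()),
        )
    constrained = (
        (out["q_fdr"] < fdr_alpha)
        & (syn_p >= 0.05)
        & (out["oe95"] < oe95_threshold)
    ).fillna(False)
    unconstrained = (out["p_depletion"] >= 0.05) & (out["n_observed"] >= 1)
    out["classification"] = np.select(
        [constrained.to_numpy(), unconstrained.to_numpy()],
        [CONSTRAINED, UNCONSTRAINED],
        default=INDETERMINATE,
    )
    return out


def compute_constraint(
    snvs: pd.DataFrame,
    *,
    depth_threshold: int | None = DEFAULT_DEPTH_THRESHOLD,
    fdr_alpha: float = 0.05,
    oe95_threshold: float = 0.6,
    ci_method: str = "clopper-pearson",
    fdr_family: str = "joint",
    test: str = "poisson_binomial",
    n_exact: int = N_EXACT,
    include_full_cds: bool = True,
) -> pd.DataFrame:
    """End-to-end regional nonsense constraint from an annotated SNV table.

    ``snvs`` must hold one row per possible SNV with columns
    transcript_id, region, consequence, scaled_rate, observed (and
    median_depth when depth filtering is on). For every transcript x
    region (plus a ``full_cds`` group) the nonsense depletion tail, O/E,
    OE95 and the synonymous veto are computed; BH-FDR is applied across
    nonsense tests (``fdr_family``: "joint" across all rows or
    "per_region"); regions are then classified.

    ``test="binomial"`` replaces the Poisson-binomial tail with a plain
    binomial CDF at the mean scaled rate (sensitivity analysis).
    """
    if "scaled_rate" not in snvs or snvs["scaled_rate"].isna().any():
        raise ValueError("every SNV needs a scaled_rate")
    df = snvs
    if depth_threshold is not None:
        df = df[df["median_depth"] >= depth_threshold]

    frames = [df]
    if include_full_cds:
        whole = df.copy()
        whole["region"] = FULL_CDS
        frames.append(whole)

    rows = []
    for frame in frames:
        for (tid, region), grp in frame.groupby(["transcript_id", "region"], observed=True):
            non = grp[grp["consequence"] == NONSENSE]
            syn = grp[grp["consequence"] == SYNONYMOUS]
            if non.empty:
                continue
            n_obs = int(non["observed"].sum())
            n_poss = len(non)
            n_exp = float(non["scaled_rate"].sum())
            p_dep = _tail(non["scaled_rate"].to_numpy(), n_obs, test, n_exact)
            syn_p = (
                _tail(syn["scaled_rate"].to_numpy(), int(syn["observed"].sum()), test, n_exact)
                if len(syn)
                else float("nan")
            )
            oe, oe95 = oe_and_oe95(n_obs, n_poss, n_exp, ci_method=ci_method)
            rows.append(
                {
                    "transcript_id": tid,
                    "region": region,
                    "consequence": NONSENSE,
                    "n_possible": n_poss,
                    "n_observed": n_obs,
                    "n_expected": n_exp,
                    "oe": oe,
                    "oe95": oe95,
                    "p_depletion": p_dep,
                    "syn_p": syn_p,
                    "method": poisson_binomial_method(n_poss, n_exact=n_exact),
                }
            )
    res = pd.DataFrame(rows)
    if res.empty:
        return res
    if fdr_family == "joint":
        res["q_fdr"] = bh_fdr(res["p_depletion"].to_numpy())
    elif fdr_family == "per_region":
        res["q_fdr"] = np.nan
        for region, grp in res.groupby("region", observed=True):
            res.loc[grp.index, "q_fdr"] = bh_fdr(grp["p_depletion"].to_numpy())
    else:
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    res = classify_regions(res, fdr_alpha=fdr_alpha, oe95_threshold=oe95_threshold)
    return res.sort_values(["transcript_id", "region"], kind="mergesort", ignore_index=True)


def _tail(probs: np.ndarray, x: int, test: str, n_exact: int) -> float:
    if len(probs) == 0:
        return float("nan")
    if test == "poisson_binomial":
        return poisson_binomial_tail(probs, x, n_exact=n_exact)
    if test == "binomial":
        return float(stats.binom.cdf(x, len(probs), probs.mean()))
    raise ValueError(f"unknown test {test!r}")
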