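"""Poisson-binomial machinery, OE95, FDR and region classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nmdconstraint.constraint import (
    CONSTRAINED,
    INDETERMINATE,
    UNCONSTRAINED,
    _pb_tail_exact,
    _pb_tail_normal,
    bh_fdr,
    classify_regions,
    compute_constraint,
    oe_and_oe95,
    poisson_binomial_method,
    poisson_binomial_tail,
)


def brute_force_tail(p, x):
    """Enumerate all 2^N outcomes."""
    p = np.asarray(p, float)
    n = len(p)
    outcomes = np.arange(2**n)
    bits = (outcomes[:, None] >> np.arange(n)) & 1
    probs = np.prod(np.where(bits == 1, p, 1 - p), axis=1)
    counts = bits.sum(axis=1)
    return probs[counts <= x].sum()


class TestPoissonBinomial:
    def test_worked_example(self):
        # P(0) = 0.504, P(1) = 0.398 -> P(X<=1) = 0.902
        assert poisson_binomial_tail([0.1, 0.2, 0.3], 1) == pytest.approx(0.902, abs=1e-12)

    def test_reduces_to_binomial_cdf(self):
        p = np.full(20, 0.3)
        for x in range(21):
            assert poisson_binomial_tail(p, x) == pytest.approx(
                stats.binom.cdf(x, 20, 0.3), abs=1e-12
            )

    def test_full_support_is_one(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        assert poisson_binomial_tail(p, 50) == 1.0

    def test_exact_matches_brute_force(self):
        """DP vs enumeration, 200 random vectors with N <= 12."""
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(1, 13))
            p = rng.random(n)
            x = int(rng.integers(0, n + 1))
            assert _pb_tail_exact(p, x) == pytest.approx(brute_force_tail(p, x), abs=1e-12)

    def test_normal_approximation_near_exact_at_boundary(self):
        """Skewness-corrected normal branch within 0.005 of exact DP."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.uniform(0.01, 0.5, size=2000)
            x = int(p.sum() * rng.uniform(0.4, 1.3))
            assert _pb_tail_normal(p, x) == pytest.approx(_pb_tail_exact(p, x), abs=0.005)

    def test_branch_selection(self):
        assert poisson_binomial_method(20_000) == "exact_dp"
        assert poisson_binomial_method(20_001) == "normal_approx"

    def test_invalid_probabilities_error(self):
        with pytest.raises(ValueError):
            poisson_binomial_tail([0.1, 1.2], 1)
        with pytest.raises(ValueError):
            poisson_binomial_tail([0.1, 0.2], 3)


class TestOe95:
    def test_zero_observed_closed_form(self):
        """Clopper–Pearson upper limit at x=0 is 1 - 0.025^(1/N)."""
        oe, oe95 = oe_and_oe95(0, 1000, 10)
        assert oe == 0.0
        assert oe95 == pytest.approx((1 - 0.025 ** (1 / 1000)) * 1000 / 10, rel=1e-9)

    def test_two_of_hundred(self):
        oe, oe95 = oe_and_oe95(2, 100, 10)
        assert oe == pytest.approx(0.2)
        # CP upper bound for 2/100 ~ 0.0704, scaled by 100/10
        assert oe95 == pytest.approx(0.704, abs=0.01)

    def test_all_observed_upper_bound_property(self):
        oe, oe95 = oe_and_oe95(50, 50, 50.0)
        assert oe == pytest.approx(1.0)
        assert oe95 >= 1.0

    def test_oe95_at_least_oe(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(10, 500))
            x = int(rng.integers(0, n + 1))
            e = rng.uniform(0.5, n)
            oe, oe95 = oe_and_oe95(x, n, e)
            assert oe95 >= oe

    def test_wilson_option_and_zero_expected_flag(self):
        _, cp = oe_and_oe95(5, 100, 10, ci_method="clopper-pearson")
        _, wi = oe_and_oe95(5, 100, 10, ci_method="wilson")
        assert cp != wi
        oe, oe95 = oe_and_oe95(1, 10, 0.0)
        assert np.isnan(oe) and np.isnan(oe95)


class TestBhFdr:
    def test_step_up_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_and_boundary(self):
        assert bh_fdr([0.37]) == pytest.approx([0.37])
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])


class TestClassification:
    def _frame(self, **kw):
        base = dict(q_fdr=0.5, syn_p=0.5, oe95=0.5, p_depletion=0.5, n_observed=1)
        base.update(kw)
        return pd.DataFrame([base])

    def test_constrained_criteria(self):
        out = classify_regions(self._frame(q_fdr=0.01, syn_p=0.5, oe95=0.4, p_depletion=0.001))
        assert out["classification"].iloc[0] == CONSTRAINED

    def test_zero_observed_blocks_unconstrained(self):
        out = classify_regions(self._frame(p_depletion=0.20, n_observed=0))
        assert out["classification"].iloc[0] == INDETERMINATE

    def test_synonymous_depletion_vetoes(self):
        out = classify_regions(self._frame(q_fdr=0.01, syn_p=0.02, oe95=0.4, p_depletion=0.001))
        assert out["classification"].iloc[0] == INDETERMINATE

    def test_unconstrained(self):
        out = classify_regions(self._frame(p_depletion=0.3, n_observed=2))
        assert out["classification"].iloc[0] == UNCONSTRAINED

    def test_missing_syn_p_cannot_be_constrained(self):
        out = classify_regions(
            self._frame(q_fdr=0.01, syn_p=np.nan, oe95=0.4, p_depletion=0.001)
        )
        assert out["classification"].iloc[0] == INDETERMINATE


class TestComputeConstraint:
    def _snvs(self, rng, oe_true=1.0, n=300, tid="T1"):
        rates = np.clip(rng.lognormal(np.log(0.08), 0.5, 2 * n), 0, 1)
        cons = np.array(["nonsense"] * n + ["synonymous"] * n)
        factor = np.where(cons == "nonsense", oe_true, 1.0)
        return pd.DataFrame(
            {
                "transcript_id": tid,
                "region": "nmd_target",
                "consequence": cons,
                "scaled_rate": rates,
                "observed": rng.random(2 * n) < rates * factor,
                "median_depth": 30,
            }
        )

    def test_depleted_region_is_constrained(self):
        rng = np.random.default_rng(21)
        snvs = self._snvs(rng, oe_true=0.1, n=500)
        res = compute_constraint(snvs, include_full_cds=False)
        assert res["classification"].iloc[0] == CONSTRAINED
        assert res["oe"].iloc[0] < 0.3

    def test_neutral_region_is_unconstrained(self):
        rng = np.random.default_rng(22)
        res = compute_constraint(self._snvs(rng, oe_true=1.0), include_full_cds=False)
        assert res["classification"].iloc[0] == UNCONSTRAINED

    def test_full_cds_row_present(self):
        rng = np.random.default_rng(23)
        res = compute_constraint(self._snvs(rng), include_full_cds=True)
        assert set(res["region"]) == {"nmd_target", "full_cds"}

    def test_binomial_sensitivity_option_close_to_poisson_binomial(self):
        rng = np.random.default_rng(24)
        snvs = self._snvs(rng, oe_true=0.5)
        pb = compute_constraint(snvs, include_full_cds=False)
        bi = compute_constraint(snvs, include_full_cds=False, test="binomial")
        assert bi["p_depletion"].iloc[0] == pytest.approx(pb["p_depletion"].iloc[0], abs=0.02)

    def test_fdr_family_option(self):
        rng = np.random.default_rng(25)
        snvs = pd.concat(
            [self._snvs(rng, tid=f"T{i}", oe_true=0.5) for i in range(4)], ignore_index=True
        )
        joint = compute_constraint(snvs, include_full_cds=True, fdr_family="joint")
        per = compute_constraint(snvs, include_full_cds=True, fdr_family="per_region")
        assert joint["q_fdr"].to_numpy() == pytest.approx(
            bh_fdr(joint["p_depletion"].to_numpy())
        )
        for region, grp in per.groupby("region"):
            assert grp["q_fdr"].to_numpy() == pytest.approx(
                bh_fdr(grp["p_depletion"].to_numpy())
            )
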