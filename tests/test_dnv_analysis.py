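"""DNV filtering, deduplication, enrichment, odds ratios and the gene screen."""

import numpy as np
import pandas as pd
import pytest

from nmdconstraint.dnv_analysis import (
    DnvFilterThresholds,
    candidate_gene_screen,
    dedup_across_cohorts,
    diagnostic_odds,
    filter_dnvs,
    regional_enrichment,
)


def dnv_frame(rows, columns=None):
    cols = columns or [
        "chrom", "pos", "ref", "alt", "proband_id", "cohort", "consequence",
        "population_ac", "population_af", "cohort_ac",
    ]
    return pd.DataFrame(rows, columns=cols)


class TestFilterDnvs:
    def _base_row(self, **kw):
        row = dict(chrom="chrS", pos=100, ref="A", alt="T", proband_id="P1",
                   cohort="A", consequence="synonymous",
                   population_ac=0, population_af=0.0, cohort_ac=1)
        row.update(kw)
        return row

    def test_population_ac_threshold(self):
        df = pd.DataFrame([self._base_row(population_ac=2)])
        assert len(filter_dnvs(df)) == 0

    def test_cohort_ac_threshold(self):
        df = pd.DataFrame([self._base_row(cohort_ac=6)])
        assert len(filter_dnvs(df)) == 0

    def test_population_af_threshold(self):
        df = pd.DataFrame([self._base_row(population_af=2e-4)])
        assert len(filter_dnvs(df)) == 0

    def test_passing_record_retained_and_missing_passes(self):
        df = pd.DataFrame([self._base_row(), self._base_row(population_ac=np.nan)])
        assert len(filter_dnvs(df)) == 2

    def test_consequence_restriction(self):
        df = pd.DataFrame([self._base_row(consequence="intron_variant")])
        assert len(filter_dnvs(df)) == 0

    def test_custom_thresholds(self):
        df = pd.DataFrame([self._base_row(population_ac=3)])
        assert len(filter_dnvs(df, DnvFilterThresholds(population_ac_max=5))) == 1


class TestDedup:
    def _records(self):
        return dnv_frame(
            [
                ("chrS", 100, "A", "T", "P1", "A", "nonsense", 0, 0.0, 1),
                ("chrS", 100, "A", "T", "P2", "B", "nonsense", 0, 0.0, 1),
                ("chrS", 200, "C", "G", "P3", "B", "missense", 0, 0.0, 1),
                ("chrS", 300, "C", "G", "P4", "A", "missense", 0, 0.0, 1),
                ("chrS", 300, "C", "G", "P5", "A", "missense", 0, 0.0, 1),
            ]
        )

    def test_shared_key_kept_in_priority_cohort(self):
        out = dedup_across_cohorts(self._records(), ["A", "B"])
        kept = out[(out["pos"] == 100)]
        assert list(kept["cohort"]) == ["A"]

    def test_unique_key_kept(self):
        out = dedup_across_cohorts(self._records(), ["A", "B"])
        assert (out["pos"] == 200).sum() == 1

    def test_within_cohort_duplicates_kept(self):
        out = dedup_across_cohorts(self._records(), ["A", "B"])
        assert (out["pos"] == 300).sum() == 2

    def test_idempotent(self):
        once = dedup_across_cohorts(self._records(), ["A", "B"])
        twice = dedup_across_cohorts(once, ["A", "B"])
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )

    def test_unknown_cohort_errors(self):
        with pytest.raises(ValueError, match="priority"):
            dedup_across_cohorts(self._records(), ["A"])


def arm_dnvs(n_con, n_unc, consequence="nonsense"):
    return pd.DataFrame(
        {
            "consequence": consequence,
            "region": "nmd_target",
            "constraint": ["constrained"] * n_con + ["unconstrained"] * n_unc,
            "proband_id": "P0",
        }
    )


def expected_frame(e_con, e_unc, cls="ptv"):
    return pd.DataFrame(
        {
            "class": cls,
            "region": "all",
            "constraint": ["constrained", "unconstrained"],
            "n_expected": [e_con, e_unc],
        }
    )


class TestEnrichment:
    def test_point_estimate_arithmetic(self):
        res = regional_enrichment(arm_dnvs(20, 20), expected_frame(100, 200), n_boot=0)
        ptv = next(r for r in res if r.category == "ptv")
        assert ptv.relative_enrichment == pytest.approx(2.0)

    def test_null_ci_spans_one(self):
        res = regional_enrichment(arm_dnvs(200, 400), expected_frame(100, 200),
                                  n_boot=2000, seed=1)
        ptv = next(r for r in res if r.category == "ptv")
        assert ptv.relative_enrichment == pytest.approx(1.0, abs=0.01)
        assert ptv.ci_lo < 1.0 < ptv.ci_hi
        assert ptv.bootstrap_p > 0.05

    def test_invariant_to_uniform_expected_scaling(self):
        a = regional_enrichment(arm_dnvs(30, 50), expected_frame(100, 200), n_boot=0)
        b = regional_enrichment(arm_dnvs(30, 50), expected_frame(700, 1400), n_boot=0)
        assert a[0].relative_enrichment == pytest.approx(b[0].relative_enrichment)

    def test_zero_unconstrained_flagged_nan(self):
        res = regional_enrichment(arm_dnvs(10, 0), expected_frame(100, 200), n_boot=0)
        assert np.isnan(next(r for r in res if r.category == "ptv").relative_enrichment)

    def test_bootstrap_stability_across_seeds(self):
        """B = 2,000 with two seeds: CI endpoints agree within 5% relative."""
        dnvs = arm_dnvs(300, 300)
        exp = expected_frame(100, 200)
        a = regional_enrichment(dnvs, exp, n_boot=2000, seed=11)[0]
        b = regional_enrichment(dnvs, exp, n_boot=2000, seed=99)[0]
        assert abs(a.ci_lo - b.ci_lo) / a.ci_lo < 0.05
        assert abs(a.ci_hi - b.ci_hi) / a.ci_hi < 0.05

    def test_frameshift_pooled_with_nonsense(self):
        dnvs = pd.concat(
            [arm_dnvs(10, 10, "nonsense"), arm_dnvs(10, 10, "frameshift")],
            ignore_index=True,
        )
        res = regional_enrichment(dnvs, expected_frame(100, 100), n_boot=0)
        ptv = next(r for r in res if r.category == "ptv")
        assert ptv.dnv_constrained == 20 and ptv.dnv_unconstrained == 20


class TestDiagnosticOdds:
    def _outcomes(self, a, b, c, d):
        """a carriers solved, b carriers unsolved, c/d non-carriers."""
        probands = [f"P{i}" for i in range(a + b + c + d)]
        solved = ["yes"] * a + ["no"] * b + ["yes"] * c + ["no"] * d
        carriers = set(probands[: a + b])
        return {"cat": carriers}, pd.DataFrame(
            {"proband_id": probands, "case_solved": solved}
        )

    def test_worked_odds_ratio(self):
        carriers, outcomes = self._outcomes(30, 70, 10, 90)
        res = diagnostic_odds(carriers, outcomes, family_size=1)[0]
        assert res.odds_ratio == pytest.approx(3.857, abs=0.001)
        assert res.ci_lo < 3.857 < res.ci_hi

    def test_symmetric_table_is_null(self):
        carriers, outcomes = self._outcomes(50, 50, 50, 50)
        res = diagnostic_odds(carriers, outcomes, family_size=1)[0]
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_partially_counts_as_solved(self):
        carriers = {"cat": {"P0"}}
        outcomes = pd.DataFrame(
            {"proband_id": ["P0", "P1", "P2", "P3"],
             "case_solved": ["partially", "no", "unknown", "yes"]}
        )
        res = diagnostic_odds(carriers, outcomes, family_size=1)[0]
        # P0 solved carrier; non-carriers: 1 solved, 2 unsolved
        assert res.haldane_corrected

    def test_bonferroni_threshold_family_14(self):
        carriers, outcomes = self._outcomes(300, 700, 100, 900)
        res = diagnostic_odds(carriers, outcomes, family_size=14)[0]
        assert res.p < 0.05 / 14
        assert res.significant_bonferroni


class TestCandidateScreen:
    def _inputs(self, oe=0.25, n_obs=15, classification="constrained", n_dnvs=3):
        dnvs = pd.DataFrame(
            {
                "gene_id": ["G1"] * n_dnvs,
                "transcript_id": ["T1"] * n_dnvs,
                "region": ["distal"] * n_dnvs,
                "consequence": ["nonsense", "frameshift", "nonsense"][:n_dnvs],
                "constraint": ["constrained"] * n_dnvs,
            }
        )
        results = pd.DataFrame(
            [
                {
                    "transcript_id": "T1",
                    "region": "distal",
                    "oe": oe,
                    "n_observed": n_obs,
                    "classification": classification,
                }
            ]
        )
        return dnvs, results

    def test_qualifying_gene_is_candidate(self):
        dnvs, results = self._inputs()
        hits = candidate_gene_screen(dnvs, results)
        assert list(hits["gene_id"]) == ["G1"]

    def test_high_oe_excluded(self):
        dnvs, results = self._inputs(oe=0.35)
        assert candidate_gene_screen(dnvs, results).empty

    def test_known_gene_excluded(self):
        dnvs, results = self._inputs()
        hits = candidate_gene_screen(dnvs, results, {"panel": {"G1"}})
        assert hits.empty

    def test_too_few_dnvs_excluded(self):
        dnvs, results = self._inputs(n_dnvs=2)
        assert candidate_gene_screen(dnvs, results).empty

    def test_many_observed_nonsense_excluded(self):
        dnvs, results = self._inputs(n_obs=25)
        assert candidate_gene_screen(dnvs, results).empty
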