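"""F-index computation, severity bands, and the study golden values."""
import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abca4func import findex, fixtures, simulate
from abca4func.errors import NoCommonExperimentsError, ZeroStimulationWindowError, ZeroWildTypeSignalError
from abca4func.findex import Severity, SeverityBands


def summary_row(expr, basal, stim, expr_sd=0.0, basal_sd=0.0, stim_sd=0.0, vid="v"):
    return {
        "variant_id": vid,
        "rel_expression_mean": expr, "rel_expression_sd": expr_sd,
        "rel_basal_mean": basal, "rel_basal_sd": basal_sd,
        "rel_stimulated_mean": stim, "rel_stimulated_sd": stim_sd,
    }


WT = summary_row(100, 100, 171, stim_sd=14, vid="WT")


class TestComponents:
    def test_E_is_expression_ratio(self):
        assert findex.compute_E(summary_row(72, 58, 56), WT) == pytest.approx(0.72)
        assert findex.compute_E(summary_row(43, 70, 99), WT) == pytest.approx(0.43)
        assert findex.compute_E(WT, WT) == 1.0

    def test_E_rejects_nonpositive_wt(self):
        with pytest.raises(ZeroWildTypeSignalError):
            findex.compute_E(summary_row(50, 0, 0), summary_row(0, 100, 171, vid="WT"))

    def test_S_is_window_ratio(self):
        assert findex.compute_S(summary_row(72, 58, 56), WT) == pytest.approx(-2 / 71)
        assert findex.compute_S(summary_row(100, 120, 120), WT) == 0.0
        assert findex.compute_S(WT, WT) == 1.0

    def test_S_rejects_zero_wt_window(self):
        flat_wt = summary_row(100, 100, 100, vid="WT")
        with pytest.raises(ZeroStimulationWindowError):
            findex.compute_S(summary_row(50, 60, 80), flat_wt)

    def test_F_is_the_product(self):
        assert findex.compute_findex(0.5, 0.5) == 0.25
        assert round(findex.compute_findex(0.72, -2 / 71), 2) == -0.02
        assert findex.compute_findex(1.0, 1.0) == 1.0

    @given(
        E=st.floats(min_value=-2, max_value=2),
        S=st.floats(min_value=-2, max_value=2),
    )
    @settings(derandomize=True, max_examples=50)
    def test_F_is_bilinear(self, E, S):
        assert findex.compute_findex(2 * E, S) == pytest.approx(2 * findex.compute_findex(E, S))
        assert findex.compute_findex(E, -S) == pytest.approx(-findex.compute_findex(E, S))


class TestSeverity:
    @pytest.mark.parametrize(
        "F,expected",
        [
            (-0.02, Severity.SEVERE),
            (0.0, Severity.SEVERE),
            (0.1499, Severity.SEVERE),
            (0.15, Severity.MODERATE),
            (0.48, Severity.MODERATE),
            (0.50, Severity.MODERATE),
            (0.60, Severity.INDETERMINATE),
            (0.6999, Severity.INDETERMINATE),
            (0.70, Severity.NORMAL_MILD),
            (1.35, Severity.NORMAL_MILD),
        ],
    )
    def test_default_bands(self, F, expected):
        assert findex.categorize_severity(F) is expected

    def test_bands_are_configurable_and_validated(self):
        tight = SeverityBands(severe_max=0.1, moderate_max=0.4, normal_min=0.8)
        assert findex.categorize_severity(0.45, tight) is Severity.INDETERMINATE
        with pytest.raises(ValueError):
            SeverityBands(severe_max=0.5, moderate_max=0.4)

    def test_published_findex_column_severity_census(self, published_summary):
        """The ten study F values split 2 severe / 3 moderate / 5 normal-mild."""
        study = published_summary.drop(fixtures.WT_ID)
        cats = [findex.categorize_severity(f) for f in study["F_printed"]]
        census = {s: cats.count(s) for s in Severity}
        assert census[Severity.SEVERE] == 2
        assert census[Severity.MODERATE] == 3
        assert census[Severity.NORMAL_MILD] == 5
        assert census[Severity.INDETERMINATE] == 0


class TestPerReplicate:
    def test_wt_identical_replicates_give_F_one_sd_zero(self):
        spec = simulate.SimulationSpec(
            variants=(simulate.VariantSpec("v", 1.0, 1.0),),
            n_replicates=3, cv_expression=0.0, cv_luminescence=0.0, seed=1,
        )
        fi = simulate.run_pipeline(*simulate.simulate_assays(spec)).set_index("variant_id")
        assert fi.loc["v", "F"] == pytest.approx(1.0)
        assert fi.loc["v", "F_sd"] == 0.0
        assert fi.loc["v", "severity"] == "normal_mild"

    def test_mean_of_replicate_F_values(self):
        # E fixed at 1, per-experiment S values 0.40/0.50/0.54
        expr = pd.DataFrame({"variant_id": ["WT"] * 3 + ["v"] * 3,
                             "experiment_id": ["E1", "E2", "E3"] * 2,
                             "rel_expression": [100.0] * 6})
        atp = pd.DataFrame({"variant_id": ["WT"] * 3 + ["v"] * 3,
                            "experiment_id": ["E1", "E2", "E3"] * 2,
                            "rel_basal": [100.0] * 6,
                            "rel_stimulated": [200.0] * 3 + [140.0, 150.0, 154.0]})
        fi = findex.findex_per_replicate(expr, atp).set_index("variant_id")
        assert fi.loc["v", "F"] == pytest.approx(0.48)

    def test_no_common_experiments_raises(self):
        expr = pd.DataFrame({"variant_id": ["WT", "v"], "experiment_id": ["E1", "E1"],
                             "rel_expression": [100.0, 50.0]})
        atp = pd.DataFrame({"variant_id": ["WT", "v"], "experiment_id": ["E1", "E2"],
                            "rel_basal": [100.0, 80.0], "rel_stimulated": [171.0, 90.0]})
        with pytest.raises(NoCommonExperimentsError, match="v"):
            findex.findex_per_replicate(expr, atp)

    def test_agrees_with_from_means_on_noiseless_replicates(self):
        spec = simulate.SimulationSpec(
            variants=(simulate.VariantSpec("a", 0.72, -0.028), simulate.VariantSpec("b", 1.2, 0.4)),
            n_replicates=4, cv_expression=0.0, cv_luminescence=0.0, seed=7,
        )
        tables = simulate.simulate_assays(spec)
        per_rep = simulate.run_pipeline(*tables, method="per_replicate").set_index("variant_id")
        from_means = simulate.run_pipeline(*tables, method="from_means").set_index("variant_id")
        for vid in ("a", "b"):
            assert per_rep.loc[vid, "F"] == pytest.approx(from_means.loc[vid, "F"], abs=1e-12)


class TestDeltaMethodSd:
    def test_hand_computed_propagation(self):
        row = summary_row(80, 90, 140, expr_sd=8, basal_sd=9, stim_sd=12)
        E, S = 0.8, 50 / 71
        expected = math.sqrt(
            (S * 8 / 100) ** 2 + (E * 12 / 71) ** 2 + (E * 9 / 71) ** 2 + (E * S * 14 / 71) ** 2
        )
        assert findex.propagate_f_sd(row, WT) == pytest.approx(expected)

    def test_zero_sds_propagate_to_zero(self):
        row = summary_row(80, 90, 140)
        wt = summary_row(100, 100, 171, vid="WT")
        assert findex.propagate_f_sd(row, wt) == 0.0


class TestStudyGoldenValues:
    """Recomputation of the published functional table from fixture replicates."""

    def test_per_replicate_F_matches_published_column_to_2dp(self, study_findex, published_summary):
        for _, row in study_findex.iterrows():
            want = published_summary.loc[row["variant_id"], "F_printed"]
            assert round(row["F"], 2) == pytest.approx(want), row["variant_id"]

    def test_summaries_round_to_published_values(self, study_summary, published_summary):
        cols = ["rel_expression_mean", "rel_expression_sd", "rel_basal_mean",
                "rel_basal_sd", "rel_stimulated_mean", "rel_stimulated_sd"]
        for _, row in study_summary.iterrows():
            want = published_summary.loc[row["variant_id"]]
            for col in cols:
                assert abs(row[col] - want[col]) <= 0.5, (row["variant_id"], col)

    def test_from_means_F_tracks_published_column(self, study_summary, published_summary):
        """From-means F agrees with the replicate-averaged published column to
        within the averaging discrepancy observed in the published data
        (largest 0.10); exact at 2 dp for Asn415Thr and WT."""
        fi = findex.findex_from_summaries(study_summary, fixtures.WT_ID).set_index("variant_id")
        for vid, row in fi.iterrows():
            want = published_summary.loc[vid, "F_printed"]
            assert abs(row["F"] - want) <= 0.11, vid
        assert round(fi.loc["c.1244A>C", "F"], 2) == -0.02  # Asn415Thr
        assert round(fi.loc[fixtures.WT_ID, "F"], 2) == 1.00

    def test_severity_matches_published_labels(self, study_findex, published_summary):
        for _, row in study_findex.iterrows():
            want = published_summary.loc[row["variant_id"], "severity_printed"]
            assert Severity(row["severity"]).label == want

    def test_wt_fold_stimulation_is_1p7(self, study_summary):
        wt = study_summary.set_index("variant_id").loc[fixtures.WT_ID]
        ratio = wt["rel_stimulated_mean"] / wt["rel_basal_mean"]
        assert round(ratio, 1) == 1.7
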