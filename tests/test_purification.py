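"""Efficiency-corrected His-skew and heterogeneity estimators."""

import logging

import numpy as np
import pandas as pd
import pytest

from rubiscohet import purification as pq
from rubiscohet.synthetic import (
    AssemblyScenario,
    ColumnEfficiencyModel,
    NoiseModel,
    simulate_experiment,
)
from conftest import make_records


def run_simulated(p, columns, noise, n_rep=3, n_holo=50_000, seed=2, alpha=1.0):
    scenario = AssemblyScenario(skew_p=p, preference_alpha=alpha, n_holoenzymes=n_holo)
    records, truth = simulate_experiment(scenario, columns, noise, n_replicates=n_rep, seed=seed)
    corrected = pq.correct_amounts(records)
    return records, truth, corrected


class TestEstimateEfficiencies:
    def test_stage_ratio_arithmetic(self, perfect_column_records):
        rec = perfect_column_records.copy()
        rec.loc[(rec.stage == "post_his") & (rec.antibody == "anti_his"), "intensity"] = 80.0
        eff = pq.estimate_efficiencies(rec)
        assert eff.loc["r1", "e_his"] == pytest.approx(0.8)
        assert eff.loc["r1", "e_strep"] == pytest.approx(1.0)

    def test_configured_efficiencies_recovered_from_noise_free_simulation(self):
        cols = ColumnEfficiencyModel(e_his=0.7, e_strep=0.85)
        records, _, _ = run_simulated(0.5, cols, NoiseModel())
        eff = pq.estimate_efficiencies(records)
        np.testing.assert_allclose(eff["e_his"], 0.7, rtol=1e-12)
        np.testing.assert_allclose(eff["e_strep"], 0.85, rtol=1e-12)

    def test_zero_denominator_excludes_replicate(self, perfect_column_records, caplog):
        rec = perfect_column_records.copy()
        rec.loc[(rec.stage == "soluble") & (rec.antibody == "anti_his"), "intensity"] = 0.0
        with caplog.at_level(logging.WARNING):
            eff = pq.estimate_efficiencies(rec)
        assert bool(eff.loc["r1", "excluded"])
        assert "excluded" in caplog.text

    def test_noisy_ratio_above_one_is_capped_with_warning(self, perfect_column_records, caplog):
        rec = perfect_column_records.copy()
        rec.loc[(rec.stage == "post_strep") & (rec.antibody == "anti_strep"), "intensity"] = 72.0
        with caplog.at_level(logging.WARNING):
            eff = pq.estimate_efficiencies(rec)
        assert eff.loc["r1", "e_strep"] == 1.0
        assert "capped" in caplog.text
        uncapped = pq.estimate_efficiencies(rec, cap_at_one=False)
        assert uncapped.loc["r1", "e_strep"] == pytest.approx(1.2)

    def test_duplicate_rows_rejected(self, perfect_column_records):
        dup = pd.concat([perfect_column_records, perfect_column_records.iloc[[0]]])
        with pytest.raises(ValueError):
            pq.estimate_efficiencies(dup)


class TestCorrectAmounts:
    def test_perfect_columns_worked_example(self, perfect_column_records):
        corr = pq.correct_amounts(perfect_column_records)
        assert corr.loc["r1", "a_hetero"] == pytest.approx(60.0)
        assert corr.loc["r1", "a_total_initial"] == pytest.approx(140.0)
        het = pq.measured_heterogeneity(corr)
        assert het.per_replicate.loc["r1"] == pytest.approx(60 / 140, abs=1e-12)

    def test_simulator_truth_recovered_under_constant_efficiency(self):
        cols = ColumnEfficiencyModel(e_his=0.8, e_strep=0.9)
        _, truth, corrected = run_simulated(0.6, cols, NoiseModel())
        het = pq.measured_heterogeneity(corrected)
        np.testing.assert_allclose(
            het.per_replicate.to_numpy(),
            truth.set_index("replicate").loc[het.per_replicate.index,
                                             "true_heterogeneous_fraction"].to_numpy(),
            atol=1e-9,
        )

    def test_inconsistent_dual_amount_flagged_not_dropped(self, perfect_column_records, caplog):
        rec = perfect_column_records.copy()
        # corrected dual amount (60) exceeds the Strep-tagged initial amount (50)
        rec.loc[(rec.stage == "soluble") & (rec.antibody == "anti_strep"), "intensity"] = 50.0
        with caplog.at_level(logging.WARNING):
            corr = pq.correct_amounts(rec)
        assert bool(corr.loc["r1", "flagged"])
        assert "r1" in corr.index

    def test_flow_through_rows_are_ignored(self, perfect_column_records):
        extra = make_records([("r1", "flow_through", "anti_his", 55.0)])
        with_ft = pd.concat([perfect_column_records, extra], ignore_index=True)
        pd.testing.assert_frame_equal(
            pq.correct_amounts(with_ft), pq.correct_amounts(perfect_column_records)
        )


class TestSkewAndHeterogeneity:
    def test_worked_skew_ratio(self, perfect_column_records):
        corr = pq.correct_amounts(perfect_column_records)
        # tag-level total: 100 / (100 + 100)
        assert pq.his_skew(corr).p_hat == pytest.approx(0.5)
        corr2 = corr.assign(a_his_initial=75.0, a_total_initial=100.0)
        assert pq.his_skew(corr2, total="inclusion_exclusion").p_hat == pytest.approx(0.75)

    def test_skew_round_trip_with_tag_proportional_signal(self):
        cols = ColumnEfficiencyModel(e_his=0.8, e_strep=0.9)
        _, truth, corrected = run_simulated(0.6, cols, NoiseModel(signal_mode="per_tag"))
        est = pq.his_skew(corrected).p_hat
        assert est == pytest.approx(truth["true_skew"].mean(), abs=1e-9)

    def test_scale_invariance_per_replicate(self):
        cols = ColumnEfficiencyModel(e_his=0.8, e_strep=0.9)
        records, _, corrected = run_simulated(0.55, cols, NoiseModel(densitometry_cv=0.05))
        scaled = records.copy()
        for i, rep in enumerate(scaled["replicate"].unique()):
            scaled.loc[scaled.replicate == rep, "intensity"] *= 10.0 ** (i - 1)
        corr_scaled = pq.correct_amounts(scaled)
        np.testing.assert_allclose(
            pq.measured_heterogeneity(corr_scaled).per_replicate,
            pq.measured_heterogeneity(corrected).per_replicate,
            rtol=1e-12,
        )
        assert pq.his_skew(corr_scaled).p_hat == pytest.approx(pq.his_skew(corrected).p_hat, rel=1e-12)

    def test_label_swap_symmetry(self):
        """Swapping His and Strep roles (pool at 1-p, mirrored efficiencies)
        mirrors the skew and leaves heterogeneity unchanged."""
        tag_signal = NoiseModel(signal_mode="per_tag")
        _, _, corr_a = run_simulated(0.6, ColumnEfficiencyModel(0.8, 0.9), tag_signal, n_holo=100_000)
        _, _, corr_b = run_simulated(0.4, ColumnEfficiencyModel(0.9, 0.8), tag_signal, n_holo=100_000)
        p_a, p_b = pq.his_skew(corr_a).p_hat, pq.his_skew(corr_b).p_hat
        assert p_b == pytest.approx(1.0 - p_a, abs=0.01)
        # heterogeneity (complex-count signal) is invariant under the swap
        _, _, het_a = run_simulated(0.6, ColumnEfficiencyModel(0.8, 0.9), NoiseModel(), n_holo=100_000)
        _, _, het_b = run_simulated(0.4, ColumnEfficiencyModel(0.9, 0.8), NoiseModel(), n_holo=100_000)
        assert pq.measured_heterogeneity(het_b).mean == pytest.approx(
            pq.measured_heterogeneity(het_a).mean, abs=0.01
        )

    def test_unbiased_under_constant_efficiency(self):
        cols = ColumnEfficiencyModel(e_his=0.8, e_strep=0.9)
        _, truth, corrected = run_simulated(0.5, cols, NoiseModel(), n_rep=6)
        het = pq.measured_heterogeneity(corrected)
        assert abs(het.mean - truth["true_heterogeneous_fraction"].mean()) < 0.01

    def test_per_tag_efficiency_causes_underestimation(self):
        cols = ColumnEfficiencyModel(tag_dependence="per_tag", q_his=0.3, q_strep=0.3)
        _, truth, corrected = run_simulated(0.6, cols, NoiseModel(), n_rep=6, n_holo=100_000)
        het = pq.measured_heterogeneity(corrected)
        assert het.mean < truth["true_heterogeneous_fraction"].mean()

    def test_zero_total_raises(self, perfect_column_records):
        corr = pq.correct_amounts(perfect_column_records).assign(a_total_initial=0.0)
        with pytest.raises(ValueError):
            pq.measured_heterogeneity(corr)


class TestCompareMeasuredVsPredicted:
    def test_binomial_truth_centers_difference_at_zero(self):
        cols = ColumnEfficiencyModel(e_his=0.9, e_strep=0.9)
        _, _, corrected = run_simulated(0.5, cols, NoiseModel(signal_mode="per_tag"),
                                        n_rep=6, n_holo=100_000)
        skew = pq.his_skew(corrected)
        # heterogeneity needs complex-count signal: recompute on the same pools
        _, _, corr_h = run_simulated(0.5, cols, NoiseModel(), n_rep=6, n_holo=100_000)
        het = pq.measured_heterogeneity(corr_h)
        report = pq.compare_measured_vs_predicted(skew, het)
        assert abs(report["mean_difference"]) < 0.01

    def test_homogeneity_preference_flags_predicted_above_measured(self):
        cols = ColumnEfficiencyModel(e_his=0.9, e_strep=0.9)
        _, _, corr_s = run_simulated(0.5, cols, NoiseModel(signal_mode="per_tag"),
                                     n_rep=6, n_holo=100_000, alpha=4.0)
        _, _, corr_h = run_simulated(0.5, cols, NoiseModel(), n_rep=6, n_holo=100_000, alpha=4.0)
        report = pq.compare_measured_vs_predicted(
            pq.his_skew(corr_s), pq.measured_heterogeneity(corr_h)
        )
        assert report["predicted_exceeds_measured"]
        assert report["mean_difference"] > 0.02

    def test_mismatched_replicate_sets_rejected(self, perfect_column_records):
        corr = pq.correct_amounts(perfect_column_records)
        skew = pq.his_skew(corr)
        het = pq.measured_heterogeneity(pd.concat([corr, corr.rename(index={"r1": "r2"})]))
        with pytest.raises(ValueError):
            pq.compare_measured_vs_predicted(skew, het)
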