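import json

import numpy as np
import pytest

import twistpg as tw
from twistpg.report import avoided_events_from_estimate
from test_combine import CLOPIDOGREL


class TestAvoidedEvents:
    @pytest.mark.parametrize("beta,person_years,count", [
        (0.33, 5264, 17),   # clopidogrel RGMTE
        (0.30, 5264, 16),   # clopidogrel RGMTE/MR combined
        (0.28, 5264, 15),   # clopidogrel GMTE(1)
        (0.037, 278_409, 103),   # statin e4e4 RGMTE
        (0.046, 278_409, 128),   # statin e2e3 MR
        (0.014, 278_409, 39),    # statin e4e4 RGMTE/MR combined
    ])
    def test_printed_hazard_differences_give_printed_event_counts(self, beta, person_years, count):
        res = tw.avoided_events(beta, 0.0, person_years)
        assert res.magnitude == count

    def test_zero_hazard_difference_means_zero_events(self):
        assert tw.avoided_events(0.0, 0.5, 1000).count == 0

    def test_sign_preserved_with_magnitude_field(self):
        res = tw.avoided_events(-0.037, 0.018, 278_409)
        assert res.count == -103
        assert res.magnitude == 103
        assert res.ci == (-201, -5)

    def test_interval_from_plus_minus_1_96_se(self):
        res = tw.avoided_events(0.037, 0.018, 278_409)
        assert res.count == 103
        assert res.ci == (5, 201)

    def test_rounding_is_half_away_from_zero_at_final_step_only(self):
        assert tw.avoided_events(0.5, 0.0, 100).count == 1
        assert tw.avoided_events(-0.5, 0.0, 100).count == -1
        assert tw.avoided_events(0.49, 0.0, 100).count == 0

    def test_count_scales_linearly_in_person_years_before_rounding(self):
        small = tw.avoided_events(0.2, 0.0, 10_000)
        large = tw.avoided_events(0.2, 0.0, 100_000)
        assert large.count == 10 * small.count

    def test_scale_contract_enforced_for_estimates(self, rng):
        from conftest import random_dataset

        est = tw.gmte1(random_dataset(rng))  # mean difference, not % hazard
        with pytest.raises(tw.ScaleMismatchError):
            avoided_events_from_estimate(est, 1000)

    def test_nonpositive_person_years_rejected(self):
        with pytest.raises(tw.ValidationError):
            tw.avoided_events(0.3, 0.1, 0)


class TestForestPlot:
    def test_clopidogrel_plot_marks_one_passing_combination(self, tmp_path):
        results = tw.enumerate_twist(CLOPIDOGREL)
        # wrap tuples as Estimates so the plot has betas/SEs for singles
        from twistpg.estimators import ASSUMPTIONS, Estimate, two_sided_p

        for lab, (_, b, s) in CLOPIDOGREL.items():
            results[lab] = Estimate(lab, b, s, two_sided_p(b, s), 0, ASSUMPTIONS[lab], "summary")
        gmte0 = Estimate("GMTE0", -0.0039, 0.0075, 0.61, 0, ASSUMPTIONS["GMTE0"], "summary")
        out = tw.forest_plot(results, tmp_path / "forest.png", gmte0=gmte0)
        assert out.exists() and out.stat().st_size > 0
        passing = [r for k, r in results.items() if "/" in k and r.passed]
        assert len(passing) == 1

    def test_rendering_is_byte_stable_for_fixed_inputs(self, tmp_path):
        from twistpg.estimators import ASSUMPTIONS, Estimate, two_sided_p

        results = {}
        for lab, (_, b, s) in CLOPIDOGREL.items():
            results[lab] = Estimate(lab, b, s, two_sided_p(b, s), 0, ASSUMPTIONS[lab], "summary")
        p1 = tw.forest_plot(results, tmp_path / "a.png")
        p2 = tw.forest_plot(results, tmp_path / "b.png")
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_results_rejected(self, tmp_path):
        with pytest.raises(tw.ValidationError):
            tw.forest_plot({}, tmp_path / "x.png")


class TestPipeline:
    def test_end_to_end_on_simulated_cohort(self, tmp_path):
        data = tw.simulate_dataset(tw.scenario_preset(3, n=4000, seed=42))
        csv = tmp_path / "cohort.csv"
        tw.write_dataset(data, csv)
        config = {
            "data": str(csv),
            "columns": {"G": "G", "T": "T", "Y": "Y"},
            "covariates": ["Z"],
            "outcome_type": "continuous",
            "alpha": 0.05,
            "plot": "forest.png",
        }
        bundle = tw.run_pipeline(config, out_dir=tmp_path / "out")
        assert set(bundle["singles"]) == {"CAT", "GMTE1", "RGMTE", "MR"}
        assert len(bundle["combined"]) == 5
        assert bundle["gmte0"]["label"] == "GMTE0"
        assert len(bundle["diagnostics"]) == 5
        assert (tmp_path / "out" / "results.json").exists()
        assert (tmp_path / "out" / "results.csv").exists()
        assert (tmp_path / "out" / "forest.png").exists()
        # under scenario-3-style data all estimators target the same quantity
        betas = [rec["beta"] for rec in bundle["singles"].values()]
        assert np.ptp(betas) < 0.5

    def test_rerun_on_identical_inputs_is_identical(self, tmp_path):
        data = tw.simulate_dataset(tw.scenario_preset(2, n=1500, seed=5))
        csv = tmp_path / "cohort.csv"
        tw.write_dataset(data, csv)
        config = {"data": str(csv), "columns": {"G": "G", "T": "T", "Y": "Y"},
                  "covariates": ["Z"]}
        b1 = tw.run_pipeline(config, out_dir=tmp_path / "o1")
        b2 = tw.run_pipeline(config, out_dir=tmp_path / "o2")
        assert json.dumps(b1, sort_keys=True, default=str) == json.dumps(b2, sort_keys=True, default=str)

    def test_summary_only_mode_reproduces_printed_combined_row(self):
        config = {"summary": [
            {"label": "CAT", "beta": 2.2, "se": 0.210},
            {"label": "GMTE0", "beta": -0.0039, "se": 0.0075},
            {"label": "GMTE1", "beta": 0.28, "se": 0.140},
            {"label": "MR", "beta": 0.29, "se": 0.110},
            {"label": "RGMTE", "beta": 0.33, "se": 0.160},
        ]}
        bundle = tw.run_pipeline(config)
        row = bundle["combined"]["RGMTE/MR"]
        assert round(row["beta"], 1) == 0.3
        assert row["combine"] is True
        others = [v for k, v in bundle["combined"].items() if k != "RGMTE/MR"]
        assert all(v["combine"] is False for v in others)
        assert bundle["gmte0"]["beta"] == -0.0039

    def test_missing_outcome_column_is_stage_tagged(self, tmp_path):
        csv = tmp_path / "bad.csv"
        csv.write_text("G,T\n1,1\n0,0\n")
        config = {"data": str(csv), "columns": {"G": "G", "T": "T", "Y": "Y"}}
        with pytest.raises(tw.StageError) as exc:
            tw.run_pipeline(config)
        assert exc.value.stage == "read"
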