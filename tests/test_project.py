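"""Scenario projection, national aggregation, growth and inequality."""

import numpy as np
import pandas as pd
import pytest

from geotree_le.mlm import fit_mlm, predict
from geotree_le.project import (
    decadal_change,
    inequality_metrics,
    national_le,
    project_regions,
)
from geotree_le.synthetic import SyntheticTruth, make_panel, make_scenario


@pytest.fixture(scope="module")
def fitted_world():
    truth = SyntheticTruth()
    panel = make_panel(truth)
    fit = fit_mlm(panel)
    env_types = panel.groupby("region")["env_type"].first()
    return truth, panel, fit, env_types


class TestProjectRegions:
    def test_identity_scenario_equals_in_sample_predictions(self, fitted_world):
        _, panel, fit, env_types = fitted_world
        last = panel[panel["year"] == 2020].reset_index(drop=True)
        scenario = make_scenario(panel, 2030, drift={})  # zero drift
        proj = project_regions(fit, scenario, env_types)
        insample = predict(fit, last, level=0.95)
        np.testing.assert_allclose(proj["le_hat"], insample["fit"], atol=1e-9)

    def test_positive_drift_raises_projected_mean(self):
        """Continued upward covariate drift lifts mean projected LE above
        the last observed mean in essentially every replicate."""
        wins = 0
        nrep = 20
        for rep in range(nrep):
            truth = SyntheticTruth(seed=400 + rep)
            panel = make_panel(truth)
            fit = fit_mlm(panel)
            env_types = panel.groupby("region")["env_type"].first()
            proj = project_regions(fit, make_scenario(panel, 2030), env_types)
            wins += proj["le_hat"].mean() > panel.loc[panel.year == 2020,
                                                      "le"].mean()
        assert wins >= 0.95 * nrep

    def test_stage_reclassified_from_scenario_urbanization(self, fitted_world):
        _, panel, fit, env_types = fitted_world
        scenario = make_scenario(panel, 2030, drift={})
        region = int(scenario["region"].iloc[0])
        scenario.loc[scenario.region == region, "urbanization"] = 95.0
        proj = project_regions(fit, scenario, env_types)
        row = proj[proj.region == region]
        assert int(row["stage"].iloc[0]) == 3
        # the stage-3 BLUP is applied: shifting only the stage changes the
        # prediction by exactly the BLUP difference
        scenario2 = scenario.copy()
        scenario2.loc[scenario2.region == region, "urbanization"] = 50.0
        proj2 = project_regions(fit, scenario2, env_types)
        delta = (row["le_hat"].iloc[0]
                 - proj2[proj2.region == region]["le_hat"].iloc[0])
        assert delta == pytest.approx(fit.blups["stage"][3]
                                      - fit.blups["stage"][2], abs=1e-9)

    def test_missing_covariate_schema_error(self, fitted_world):
        _, panel, fit, env_types = fitted_world
        scenario = make_scenario(panel, 2030).drop(columns=["oop"])
        with pytest.raises(ValueError, match="oop"):
            project_regions(fit, scenario, env_types)

    def test_interval_brackets_point(self, fitted_world):
        _, panel, fit, env_types = fitted_world
        proj = project_regions(fit, make_scenario(panel, 2030), env_types)
        assert (proj["lo"] <= proj["le_hat"]).all()
        assert (proj["le_hat"] <= proj["hi"]).all()


class TestNationalLE:
    def _proj(self, le, se=None):
        le = np.asarray(le, float)
        return pd.DataFrame({"le_hat": le,
                             "se": se if se is not None else np.zeros_like(le)})

    def test_equal_weights_average(self):
        out = national_le(self._proj([70.0, 80.0]), weights=[1.0, 1.0])
        assert out["le"] == 75.0

    def test_single_region_holds_all_population(self):
        out = national_le(self._proj([70.0, 80.0]), weights=[0.0, 5.0])
        assert out["le"] == 80.0

    def test_population_share_weights_hand_computed(self):
        # population shares of the three environment types: 75.8/23.6/0.6 %
        le = np.array([78.0, 74.0, 70.0])
        w = np.array([0.758, 0.236, 0.006])
        out = national_le(self._proj(le), weights=w)
        assert out["le"] == pytest.approx(float(w @ le))  # 77.06

    def test_variance_propagation_independent_regions(self):
        out = national_le(self._proj([70.0, 80.0], se=[1.0, 2.0]),
                          weights=[0.5, 0.5], level=0.95)
        assert out["se"] == pytest.approx(np.sqrt(0.25 * 1 + 0.25 * 4))
        assert out["lo"] < out["le"] < out["hi"]

    def test_zero_total_weight_rejected(self):
        with pytest.raises(ValueError):
            national_le(self._proj([70.0, 80.0]), weights=[0.0, 0.0])

    def test_national_within_regional_range(self, fitted_world):
        _, panel, fit, env_types = fitted_world
        proj = project_regions(fit, make_scenario(panel, 2030), env_types)
        out = national_le(proj)
        assert proj["le_hat"].min() <= out["le"] <= proj["le_hat"].max()


class TestDecadalChange:
    def test_hand_case(self):
        out = decadal_change(pd.Series({2000: 70.0, 2010: 77.0}))
        assert out["increase_years"].iloc[0] == pytest.approx(7.0)
        assert out["growth_pct"].iloc[0] == pytest.approx(10.0)

    def test_constant_series(self):
        out = decadal_change(pd.Series({2000: 75.0, 2010: 75.0, 2020: 75.0}))
        assert (out["increase_years"] == 0).all()
        assert (out["growth_pct"] == 0).all()

    def test_telescoping_total(self):
        s = pd.Series({2000: 70.0, 2010: 72.5, 2020: 76.0, 2030: 80.05})
        out = decadal_change(s)
        assert out["increase_years"].sum() == pytest.approx(s[2030] - s[2000])

    def test_gap_rejected(self):
        with pytest.raises(ValueError, match="2010"):
            decadal_change(pd.Series({2000: 70.0, 2020: 75.0}))


class TestInequality:
    def test_all_equal_gives_zeros(self):
        out = inequality_metrics([75.0, 75.0, 75.0])
        assert out == {"range": 0.0, "sd": 0.0, "cv": 0.0, "gini": 0.0}

    def test_two_region_hand_oracle(self):
        # mean 75, population-weighted SD 5, CV 1/15, Gini 10/(2*2*75)
        out = inequality_metrics([70.0, 80.0])
        assert out["range"] == 10.0
        assert out["sd"] == pytest.approx(5.0)
        assert out["cv"] == pytest.approx(1 / 15)
        assert out["gini"] == pytest.approx(1 / 30)

    def test_scale_and_permutation_and_normalization_invariance(self, rng):
        le = rng.uniform(65, 85, 12)
        w = rng.uniform(1, 10, 12)
        base = inequality_metrics(le, w)
        scaled = inequality_metrics(3.0 * le, w)
        assert scaled["cv"] == pytest.approx(base["cv"])
        assert scaled["gini"] == pytest.approx(base["gini"])
        perm = rng.permutation(12)
        assert inequality_metrics(le[perm], w[perm])["gini"] == pytest.approx(
            base["gini"])
        assert inequality_metrics(le, 7.0 * w)["sd"] == pytest.approx(
            base["sd"])

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            inequality_metrics([70.0, -1.0])

    def test_shrinking_stage_effects_reduce_cv(self):
        """A world whose stage effects shrink over decades shows declining
        cross-region CV of LE, in expectation: inequality convergence."""
        deltas = []
        for rep in range(15):
            shrink = {2000: 3.0, 2010: 1.5, 2020: 0.5}
            cvs = {}
            truth = SyntheticTruth(seed=600 + rep)
            panel = make_panel(truth)
            for yr, scale in shrink.items():
                sub = panel[panel.year == yr]
                # widen stage separation by the decade's factor
                le = sub["le"] + scale * (sub["stage"] - 2)
                cvs[yr] = inequality_metrics(le, sub["population"])["cv"]
            deltas.append(cvs[2020] - cvs[2000])
        assert np.mean(deltas) < 0
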