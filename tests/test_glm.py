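import numpy as np
import pandas as pd
import pytest

from bloodmealnet.glm import (
    AnalysisTable, fit_metric_model, metrics_table, richness_latitude_model,
    term_significance, tukey_habitat,
)
from bloodmealnet.metrics import network_summary
from conftest import mk_matrix


def _table(n_per_habitat=12, ie_offsets=None, seed=0, sd=0.05):
    """Synthetic modelling table with a controllable habitat effect."""
    rng = np.random.default_rng(seed)
    ie_offsets = ie_offsets or {}
    rows = []
    families = ["Culicidae", "Ceratopogonidae", "Glossinidae"]
    for habitat in ("Agricultural", "NearNatural", "VillageUrban"):
        for i in range(n_per_habitat):
            m = int(rng.integers(80, 400))
            S = int(rng.integers(10, 40))
            rows.append({
                "study_id": f"{habitat[:2]}{i}", "habitat": habitat,
                "abs_latitude": float(rng.uniform(0, 60)),
                "family": families[int(rng.integers(0, 3))],
                "S": S, "n_diptera": S // 2, "n_hosts": S - S // 2,
                "m": m, "log_m": float(np.log(m)), "n_bloodmeals": m,
                "IE": float(np.clip(
                    0.6 + ie_offsets.get(habitat, 0.0) + rng.normal(0, sd),
                    0, 1)),
                "H2prime": float(rng.uniform(0.2, 0.6))})
    return AnalysisTable(frame=pd.DataFrame(rows))


class TestMetricsTable:
    def test_valid_networks_become_rows(self):
        mats = [mk_matrix([[2, 1], [1, 2]], study=f"S{i}") for i in range(3)]
        table = metrics_table([network_summary(m) for m in mats])
        assert len(table) == 3
        assert table.n_excluded == 0

    def test_degenerate_networks_excluded_and_counted(self):
        good = [mk_matrix([[2, 1], [1, 2]], study=f"S{i}") for i in range(2)]
        bad = mk_matrix([[5]], study="S9")
        table = metrics_table([network_summary(m) for m in good + [bad]])
        assert len(table) == 2
        assert table.n_excluded == 1

    def test_log_matrix_size(self):
        mat = mk_matrix([[50, 25], [20, 5]])
        table = metrics_table([network_summary(mat)])
        assert table.frame["log_m"].iloc[0] == pytest.approx(np.log(100))


class TestFitMetricModel:
    def test_gaussian_deviance_equals_residual_sum_of_squares(self):
        table = _table()
        model = fit_metric_model(table, "IE")
        resid = model.result.resid
        assert model.deviance == pytest.approx(float((resid ** 2).sum()))

    def test_constant_response_gives_zero_deviance_and_slopes(self):
        table = _table()
        table.frame["IE"] = 0.5
        model = fit_metric_model(table, "IE")
        assert model.deviance == pytest.approx(0.0, abs=1e-20)
        slopes = model.result.params.drop("Intercept")
        assert np.allclose(slopes, 0.0, atol=1e-10)

    def test_recovers_injected_habitat_direction(self):
        table = _table(ie_offsets={"Agricultural": -0.15}, seed=1)
        model = fit_metric_model(table, "IE", include_interactions=False)
        params = model.result.params
        # treatment coding vs Agricultural baseline: both other habitats up
        assert params["C(habitat)[T.NearNatural]"] > 0.05
        assert params["C(habitat)[T.VillageUrban]"] > 0.05


class TestTermSignificance:
    def test_adding_a_term_never_increases_deviance(self):
        table = _table(seed=3)
        for term in ("habitat", "latitude", "S", "matrix_size", "family",
                     "family:latitude", "family:habitat"):
            tt = term_significance(table, "IE", term)
            assert tt.deviance_change >= 0.0
            assert tt.df >= 1
            assert 0.0 <= tt.p_value <= 1.0

    def test_strong_effect_detected_weak_effect_not(self):
        strong = _table(ie_offsets={"Agricultural": -0.2}, seed=5)
        assert term_significance(strong, "IE", "habitat").p_value < 1e-6
        null = _table(seed=5)
        assert term_significance(null, "IE", "habitat").p_value > 0.01

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError, match="unknown term"):
            term_significance(_table(), "IE", "altitude")


class TestTukey:
    def test_identical_group_means_give_p_near_one(self):
        table = _table(seed=7, sd=0.02)
        out = tukey_habitat(table, "IE", mode="adjusted")
        assert (out.frame["p_adj"] > 0.2).all()

    def test_extreme_separation_gives_tiny_p(self):
        table = _table(ie_offsets={"Agricultural": -0.3}, seed=8, sd=0.02)
        out = tukey_habitat(table, "IE", mode="adjusted").frame
        ag = out[(out["group1"] == "Agricultural")
                 | (out["group2"] == "Agricultural")]
        assert (ag["p_adj"] < 0.001).all()

    def test_adjusted_mode_agrees_with_reference_when_no_covariates_vary(self):
        """With covariates held constant the adjusted contrasts reduce to
        raw-mean Tukey HSD, which statsmodels provides independently."""
        table = _table(ie_offsets={"Agricultural": -0.08}, seed=9)
        table.frame["abs_latitude"] = 20.0
        table.frame["S"] = 25
        table.frame["log_m"] = 5.0
        adjusted = tukey_habitat(table, "IE", mode="adjusted").frame
        raw = tukey_habitat(table, "IE", mode="raw").frame
        merged = adjusted.merge(raw, on=["group1", "group2"],
                                suffixes=("_adj", "_raw"))
        assert np.allclose(merged["estimate_adj"], merged["estimate_raw"],
                           atol=1e-9)
        assert np.allclose(merged["p_adj_adj"], merged["p_adj_raw"],
                           atol=2e-3)


class TestRichnessLatitude:
    def test_perfect_linear_fixture_r_squared_one(self):
        table = _table(seed=11)
        table.frame["n_hosts"] = (2.0 * table.frame["abs_latitude"]
                                  + 0.01 * table.frame["n_bloodmeals"] + 3.0)
        model = richness_latitude_model(table, "host_richness")
        assert model.result.rsquared == pytest.approx(1.0)
        lat = model.summary_frame().set_index("term").loc["abs_latitude"]
        assert lat["estimate"] == pytest.approx(2.0)

    def test_null_latitude_slope_ci_covers_zero_at_nominal_rate(self):
        """With no latitude effect the 95% CI should cover 0 ~95% of the
        time; check the coverage over replicates."""
        cover = 0
        reps = 120
        for seed in range(reps):
            table = _table(n_per_habitat=8, seed=seed)
            model = richness_latitude_model(table, "diptera_richness")
            lo, hi = model.result.conf_int().loc["abs_latitude"]
            cover += lo <= 0.0 <= hi
        assert 0.88 <= cover / reps <= 1.0

    def test_unknown_response_rejected(self):
        with pytest.raises(ValueError):
            richness_latitude_model(_table(), "plant_richness")
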