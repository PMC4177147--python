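import math

import numpy as np
import pandas as pd
import pytest

from starcoal import (
    ExpansionModel,
    SimConfig,
    StatVector,
    and_distance,
    default_grid,
    empirical_tmrca_years,
    evaluate_grid,
    evaluate_scenario,
    parse_newick,
    refine_grid,
    sequential_search,
    summarize,
    tmrca_compatible,
)
from starcoal.inference import (
    PARAM_NAMES,
    FitSurface,
    ParamGrid,
    SearchDivergenceError,
    family_span_grid,
)


class TestAndDistance:
    def test_identity(self):
        x = StatVector(1.3, 0.4, 0.02)
        assert and_distance(x, x) == 0.0

    def test_worked_example(self):
        obs = StatVector(1.0, 0.5, 0.1)
        sim = StatVector(1.5, 0.4, 0.1)
        assert and_distance(sim, obs) == pytest.approx((0.5 + 0.2 + 0.0) / 3)

    def test_infinite_sim_propagates(self):
        obs = StatVector(1.0, 0.5, 0.1)
        assert math.isinf(and_distance(StatVector(math.inf, 0.5, 0.1), obs))

    def test_invalid_observation_rejected(self):
        with pytest.raises(ValueError):
            and_distance(StatVector(1, 1, 1), StatVector(math.inf, 0.5, 0.1))
        with pytest.raises(ValueError):
            and_distance(StatVector(1, 1, 1), StatVector(1.0, 0.0, 0.1))


class TestEvaluateScenario:
    def test_self_fit_is_zero(self, africa_model):
        cfg = SimConfig(n_tips=8, reps=300)
        res = evaluate_scenario(
            africa_model, StatVector(1, 1, 1).__class__(1.0, 0.5, 0.1),
            cfg, np.random.default_rng(3),
        )
        obs = res["mean"]
        res2 = evaluate_scenario(africa_model, obs, cfg, np.random.default_rng(3))
        assert res2["and"] == pytest.approx(0.0, abs=1e-12)

    def test_reps_one_is_single_replicate(self, africa_model):
        cfg = SimConfig(n_tips=8, reps=1)
        obs = StatVector(2.0, 0.16, 0.05)
        res = evaluate_scenario(africa_model, obs, cfg, np.random.default_rng(4))
        assert math.isfinite(res["and"]) or math.isinf(res["and"])

    def test_wrong_regime_scores_worse(self, europe_model, africa_model):
        cfg = SimConfig(n_tips=6, reps=500)
        star_obs = evaluate_scenario(
            europe_model, StatVector(1.0, 0.5, 0.1), cfg,
            np.random.default_rng(8),
        )["mean"]
        fit_star = evaluate_scenario(
            europe_model, star_obs, cfg, np.random.default_rng(9)
        )["and"]
        fit_const = evaluate_scenario(
            ExpansionModel(10000, 10000, 0, 0), star_obs, cfg,
            np.random.default_rng(9),
        )["and"]
        assert fit_star < fit_const


class TestTmrcaCompatibility:
    @pytest.mark.parametrize(
        "t_end,dur,max_t,expected",
        [(12000, 300, 13000, True), (12000, 3000, 13000, False),
         (13000, 0, 13000, True)],
    )
    def test_boundary_rule(self, t_end, dur, max_t, expected):
        m = ExpansionModel(10, 1000, t_end, dur)
        cfg = SimConfig(n_tips=6)
        assert tmrca_compatible(m, cfg, max_t) is expected

    def test_invalid_bound_rejected(self, africa_model):
        with pytest.raises(ValueError):
            tmrca_compatible(africa_model, SimConfig(n_tips=6), 0)


class TestEmpiricalTmrca:
    def test_snp_clock_arithmetic(self):
        t = parse_newick("(A:100,B:100);")
        cfg = SimConfig(n_tips=2)
        assert empirical_tmrca_years(t, cfg) == pytest.approx(100 / 0.264 * 30)

    def test_doubling_seq_len_halves_estimate(self):
        t = parse_newick("(A:100,B:100);")
        one = empirical_tmrca_years(t, SimConfig(n_tips=2))
        two = empirical_tmrca_years(t, SimConfig(n_tips=2, seq_len=2 * 8.8e6))
        assert two == pytest.approx(one / 2)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            empirical_tmrca_years(parse_newick("(A:0,B:0);"), SimConfig(n_tips=2))


def single_cell_grid(model):
    axes = {
        "start_n": [model.start_n],
        "end_n": [model.end_n],
        "t_end_years": [model.t_end_years],
        "duration_years": [model.duration_years],
    }
    spacing = {
        "start_n": "geometric", "end_n": "geometric",
        "t_end_years": "linear", "duration_years": "geometric",
    }
    bounds = {p: (min(axes[p]), max(max(axes[p]), min(axes[p]) + 1)) for p in axes}
    return ParamGrid(axes=axes, spacing=spacing, bounds=bounds)


class TestEvaluateGrid:
    def test_single_cell_matches_scenario(self, africa_model):
        cfg = SimConfig(n_tips=8, reps=200, seed=5)
        obs = evaluate_scenario(
            africa_model, StatVector(1.0, 0.5, 0.1), cfg,
            np.random.default_rng(0),
        )["mean"]
        grid = single_cell_grid(africa_model)
        surf = evaluate_grid(grid, obs, cfg, max_tmrca_years=20000, seed=5)
        assert len(surf.table) == 1
        direct = evaluate_scenario(
            africa_model, obs, cfg,
            np.random.default_rng(np.random.SeedSequence([5, 0, 0])),
        )
        assert surf.table["and_value"].iloc[0] == pytest.approx(direct["and"])

    def test_deterministic_given_seed(self, africa_model):
        cfg = SimConfig(n_tips=8, reps=100, seed=6)
        obs = StatVector(2.3, 0.16, 0.05)
        grid = default_grid(15000, points=2)
        a = evaluate_grid(grid, obs, cfg, 15000, seed=6).table
        b = evaluate_grid(grid, obs, cfg, 15000, seed=6).table
        pd.testing.assert_frame_equal(a, b)

    def test_incompatible_cells_excluded_before_simulation(self):
        cfg = SimConfig(n_tips=6, reps=10)
        obs = StatVector(2.0, 0.16, 0.05)
        grid = default_grid(1000.0, points=2)  # duration axis spans 30..1000
        surf = evaluate_grid(grid, obs, cfg, max_tmrca_years=1000.0, seed=1)
        bad = surf.table[
            surf.table["t_end_years"] + surf.table["duration_years"] > 1000.0
        ]
        assert bad["excluded"].all()
        assert bad["and_value"].isna().all()


class TestRefineGrid:
    def _surface_from(self, grid, and_values):
        rows = []
        for idx, params in grid.cells():
            rows.append({**params, "cell": idx, "r_s": 1.0, "m_s": 0.1,
                         "d_s": 0.01, "and_value": and_values[idx],
                         "frac_inf_r": 0.0, "excluded": False, "reason": ""})
        return FitSurface(table=pd.DataFrame(rows))

    def test_single_minimum_brackets_cell(self):
        grid = default_grid(12000.0, points=5)
        values = np.full(grid.n_cells, 1.0)
        # pick an interior cell and give it (and only it) a low AND
        target = None
        for idx, params in grid.cells():
            mids = [np.searchsorted(grid.axes[p], params[p]) for p in PARAM_NAMES]
            if all(0 < m < 4 for m in mids):
                target = (idx, params)
                break
        values[target[0]] = 0.01
        new = refine_grid(self._surface_from(grid, values), grid, min_keep=1)
        for p in PARAM_NAMES:
            assert new.axes[p][0] <= target[1][p] <= new.axes[p][-1]
            # narrowed relative to the original axis
            assert new.axes[p][-1] - new.axes[p][0] <= (
                grid.axes[p][-1] - grid.axes[p][0]
            )

    def test_boundary_minimum_extends_range_up_to_bounds(self):
        grid = ParamGrid(
            axes={"start_n": [10.0, 20.0, 40.0], "end_n": [1000.0],
                  "t_end_years": [0.0], "duration_years": [300.0]},
            spacing={"start_n": "geometric", "end_n": "geometric",
                     "t_end_years": "linear", "duration_years": "geometric"},
            bounds={"start_n": (1.0, 5000.0), "end_n": (100.0, 1e5),
                    "t_end_years": (0.0, 12000.0),
                    "duration_years": (30.0, 12000.0)},
        )
        values = np.array([0.01, 1.0, 1.0])  # minimum at the low edge
        new = refine_grid(self._surface_from(grid, values), grid, min_keep=1)
        assert new.axes["start_n"][0] < 10.0
        assert new.axes["start_n"][0] >= 1.0

    def test_all_excluded_raises(self):
        grid = single_cell_grid(ExpansionModel(10, 1000, 0, 300))
        surf = self._surface_from(grid, np.array([np.nan]))
        surf.table["excluded"] = True
        with pytest.raises(SearchDivergenceError):
            refine_grid(surf, grid)


class TestFamilySpanGrid:
    def test_family_scales_through_cell(self):
        grid = default_grid(13000.0)
        cells = pd.DataFrame([
            {"start_n": 40.0, "end_n": 2000.0, "t_end_years": 2000.0,
             "duration_years": 11000.0, "and_value": 0.01},
        ])
        fam = family_span_grid(cells, grid, max_tmrca_years=13000.0)
        # downward: clipped where end_n hits its lower bound (c = 0.05)
        assert fam.axes["start_n"][0] == pytest.approx(2.0, rel=1e-6)
        assert fam.axes["end_n"][0] == pytest.approx(100.0, rel=1e-6)
        # upward: clipped by the TMRCA cap (c = 1.0)
        assert fam.axes["t_end_years"][-1] == pytest.approx(2000.0, rel=1e-6)
        # time axes are linear in the mapping grid
        assert fam.spacing["t_end_years"] == "linear"
        assert fam.spacing["duration_years"] == "linear"


class TestSummarize:
    def test_degenerate_single_value(self):
        acc = pd.DataFrame([
            {"start_n": 2.0, "end_n": 1e4, "t_end_years": 0.0,
             "duration_years": 300.0}
        ] * 3)
        s = summarize(acc)
        assert s["start_n"]["median"] == 2.0
        assert s["start_n"]["ci_low"] == s["start_n"]["ci_high"] == 2.0
        assert s["start_n"]["histogram"] == {2.0: 3}

    def test_median_of_discrete_values(self):
        acc = pd.DataFrame({
            "start_n": [1.0, 2.0, 2.0, 3.0],
            "end_n": [1.0] * 4, "t_end_years": [0.0] * 4,
            "duration_years": [30.0] * 4,
        })
        assert summarize(acc)["start_n"]["median"] == 2.0

    def test_median_inside_interval(self):
        rng = np.random.default_rng(2)
        acc = pd.DataFrame({
            p: rng.uniform(1, 100, size=40) for p in PARAM_NAMES
        })
        s = summarize(acc)
        for p in PARAM_NAMES:
            assert s[p]["ci_low"] <= s[p]["median"] <= s[p]["ci_high"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame(columns=list(PARAM_NAMES)))


class TestSequentialSearch:
    def test_fitting_single_cell_grid_terminates_quickly(self, africa_model):
        cfg = SimConfig(n_tips=8, reps=200, seed=3)
        obs = evaluate_scenario(
            africa_model, StatVector(1.0, 0.5, 0.1), cfg,
            np.random.default_rng(np.random.SeedSequence([3, 0, 0])),
        )["mean"]
        grid = single_cell_grid(africa_model)
        res = sequential_search(obs, grid, cfg, max_tmrca_years=20000,
                                seed=3, max_rounds=2)
        assert res.accepted_mode == "absolute"
        assert len(res.accepted) >= 1
        assert res.summaries["start_n"]["median"] > 0

    def test_all_cells_excluded_signals_failure(self):
        cfg = SimConfig(n_tips=6, reps=10)
        obs = StatVector(2.0, 0.16, 0.05)
        grid = single_cell_grid(ExpansionModel(10, 1000, 12000, 3000))
        with pytest.raises(SearchDivergenceError):
            sequential_search(obs, grid, cfg, max_tmrca_years=13000,
                              seed=1, max_rounds=2)

    def test_history_and_summary_shape(self):
        cfg = SimConfig(n_tips=6, reps=50, seed=4)
        obs = StatVector(100.0, 0.17, 0.02)
        grid = default_grid(12000.0, points=3)
        res = sequential_search(obs, grid, cfg, 12000.0, seed=4, max_rounds=3)
        assert res.n_rounds <= 3
        for p in PARAM_NAMES:
            s = res.summaries[p]
            assert s["ci_low"] <= s["median"] <= s["ci_high"]
        text = res.to_json()
        assert '"summaries"' in text
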