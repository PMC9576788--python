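"""Scenarios, polarization sweeps, sensitivity maps, and parameter fitting."""

import math

import numpy as np
import pytest

import osmoengine as oe
from osmoengine.errors import ParameterError
from osmoengine.experiments import (SCENARIOS, fit_parameters,
                                    polarization_ratio, run_scenario,
                                    scenario_parameters, sensitivity_contour,
                                    set_polarization_ratio, sweep_polarization)
from osmoengine.solver import SolverOptions, solve_steady
from osmoengine.synthetic import gen_velocity_observations


# ---------------------------------------------------------------------------
# scenario resolution


def test_scenario_parameter_resolution(params):
    lat = scenario_parameters(SCENARIOS["lat_a"], params)
    assert lat.front.j_actin == 0.0

    kd = scenario_parameters(SCENARIOS["swell1_kd"], params)
    assert kd.front.alpha_cl == pytest.approx(0.1 * params.front.alpha_cl)
    assert kd.back.alpha_cl == pytest.approx(0.1 * params.back.alpha_cl)
    # knockdown preserves the polarization ratio
    assert polarization_ratio(kd, "cl") == pytest.approx(
        polarization_ratio(params, "cl"))

    sym = scenario_parameters(SCENARIOS["swell1_symmetric"], params)
    assert polarization_ratio(sym, "cl") == pytest.approx(1.0)


def test_set_polarization_ratio_modes(params):
    g0 = math.sqrt(params.front.alpha_cl * params.back.alpha_cl)
    p = set_polarization_ratio(params, 9.0, "cl", "geometric")
    assert polarization_ratio(p, "cl") == pytest.approx(9.0)
    assert math.sqrt(p.front.alpha_cl * p.back.alpha_cl) == pytest.approx(g0)
    p2 = set_polarization_ratio(params, 9.0, "cl", "hold_front")
    assert p2.front.alpha_cl == params.front.alpha_cl
    assert polarization_ratio(p2, "cl") == pytest.approx(9.0)
    with pytest.raises(ParameterError):
        set_polarization_ratio(params, -1.0, "cl")


# ---------------------------------------------------------------------------
# scenario velocities (model twins of the perturbation experiments)


@pytest.fixture(scope="module")
def scenario_v0(params, opts32):
    names = ("baseline", "swell1_front", "swell1_symmetric", "lat_a",
             "nhe1_kd", "swell1_kd", "dual_kd", "lat_a_swell1_kd")
    return {n: run_scenario(n, params, opts32).v0 for n in names}


def test_scenario_directionality(scenario_v0):
    v = scenario_v0
    assert v["baseline"] > 0
    assert v["swell1_front"] < 0  # front enrichment reverses migration
    assert abs(v["swell1_symmetric"]) < 0.3 * abs(v["baseline"])


def test_lat_a_motility_is_swell1_dependent(scenario_v0):
    """Water-driven migration persists without actin but needs SWELL1."""
    v = scenario_v0
    assert v["lat_a"] > 1e-5
    assert abs(v["lat_a_swell1_kd"]) < 0.2 * abs(v["lat_a"])
    assert abs(v["lat_a_swell1_kd"]) < 0.2 * abs(v["baseline"])


def test_dual_knockdown_is_at_least_as_slow_as_singles(scenario_v0):
    v = scenario_v0
    assert abs(v["dual_kd"]) <= min(abs(v["nhe1_kd"]), abs(v["swell1_kd"])) \
        * (1 + 1e-6)


# ---------------------------------------------------------------------------
# sweeps


@pytest.fixture(scope="module")
def small_sweep(params, opts32):
    values = np.geomspace(0.1, 10.0, 9)
    return sweep_polarization(params, values, opts32)


def test_sweep_monotone_with_one_sign_change(small_sweep):
    res = small_sweep
    assert res.converged.all()
    assert np.all(np.diff(res.v0) > 0)
    signs = np.sign(res.v0)
    assert (np.diff(signs) != 0).sum() == 1
    assert res.v0[0] < 0 < res.v0[-1]


def test_sweep_path_independence(small_sweep, params, opts32):
    """Warm-started sweep values match cold solves of the same points."""
    for idx in (0, len(small_sweep.values[0]) - 1):
        r = small_sweep.values[0][idx]
        cold = solve_steady(
            set_polarization_ratio(params, r, "cl"), opts32)
        assert cold.v0 == pytest.approx(small_sweep.v0[idx], abs=1e-9)


def test_sweep_symmetric_cell_crosses_zero_at_unity(params, opts32):
    """With every other asymmetry removed, ratio 1 is the rest state."""
    from test_solver import symmetrize

    sym = symmetrize(params)
    res = sweep_polarization(sym, np.array([0.5, 1.0, 2.0]), opts32)
    assert abs(res.v0[1]) < 1e-8
    assert res.v0[0] < 0 < res.v0[2]


def test_sweep_input_validation(params, opts32):
    with pytest.raises(ParameterError):
        sweep_polarization(params, [-1.0, 1.0], opts32)
    with pytest.raises(ParameterError):
        sweep_polarization(params, [2.0, 1.0], opts32)


def test_sweep_result_table(small_sweep):
    df = small_sweep.to_frame()
    assert list(df.columns) == ["cl_ratio", "v0", "converged"]
    assert small_sweep.provenance["grid_size"] == 32


def test_sensitivity_contour_monotone_axes(params, opts32):
    res = sensitivity_contour(params, "cl_ratio", [0.5, 1.0, 2.0],
                              "nhe_ratio", [0.8, 1.25], opts32)
    assert res.converged.all()
    # v0 nondecreasing along the SWELL1 axis at fixed NHE polarization
    assert np.all(np.diff(res.v0, axis=0) > -1e-12)
    # and along the NHE axis at fixed SWELL1 polarization
    assert np.all(np.diff(res.v0, axis=1) > -1e-12)


def test_contour_symmetric_corner_is_stationary(params, opts32):
    from test_solver import symmetrize

    sym = symmetrize(params)  # actin off, all end parameters symmetric
    res = sensitivity_contour(sym, "cl_ratio", [1.0], "nhe_ratio", [1.0], opts32)
    assert abs(res.v0[0, 0]) < 1e-8


# ---------------------------------------------------------------------------
# fitting


def test_fit_recovers_ratio_from_noise_free_observations(params, opts32):
    obs = gen_velocity_observations(params, {"baseline": {}}, n_per=5,
                                    noise_sd=0.0, seed=3, options=opts32)
    fit = fit_parameters(obs, params, {"cl_ratio": (0.5, 16.0)},
                         options=opts32, seed=3)
    truth = polarization_ratio(params, "cl")
    assert fit.values["cl_ratio"] == pytest.approx(truth, rel=1e-3)
    assert fit.ci95["cl_ratio"][0] <= truth <= fit.ci95["cl_ratio"][1]
    assert fit.rss < 1e-18


def test_fit_agrees_with_bisection_oracle(params, opts32):
    """Single observation + monotone response: fit equals root bracketing."""
    from scipy.optimize import brentq

    target_r = 2.5
    v_target = solve_steady(
        set_polarization_ratio(params, target_r, "cl"), opts32).v0
    import pandas as pd
    from osmoengine.synthetic import ObservationSet

    obs = ObservationSet(
        table=pd.DataFrame([{"condition": "baseline", "replicate": 0,
                             "v0_true": v_target, "v0_observed": v_target}]),
        conditions={"baseline": {}}, noise_sd=0.0, seed=0, n_per=1)
    fit = fit_parameters(obs, params, {"cl_ratio": (0.5, 16.0)},
                         options=opts32, seed=0)

    warm = {"s": None}

    def gap(r):
        warm["s"] = solve_steady(set_polarization_ratio(params, r, "cl"),
                                 opts32, initial=warm["s"])
        return warm["s"].v0 - v_target

    oracle = brentq(gap, 1.0, 8.0, xtol=1e-10)
    assert fit.values["cl_ratio"] == pytest.approx(oracle, rel=1e-4)


def test_fit_requires_observations(params, opts32):
    import pandas as pd
    from osmoengine.synthetic import ObservationSet

    empty = ObservationSet(table=pd.DataFrame(columns=["condition", "v0_observed"]),
                           conditions={}, noise_sd=0.0, seed=0, n_per=0)
    with pytest.raises(ParameterError):
        fit_parameters(empty, params, {"cl_ratio": (0.5, 16.0)}, options=opts32)
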