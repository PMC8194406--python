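"""MLCM estimation: design matrices, probit MLE, shape fits, prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.stats import norm

from facevoice.design import build_grid
from facevoice.observers import ObserverParams, simulate_responses
from facevoice.scales import (
    ModelSpec,
    encode_trials,
    fit_mlcm,
    fit_scale_shapes,
    predict_choice,
)

from conftest import exhaustive_design


@pytest.mark.parametrize(
    "structure, form, grid_size, n_cols",
    [
        ("independence_v", "nonparametric", (18, 19), 17),
        ("independence_a", "nonparametric", (18, 19), 18),
        ("additive", "nonparametric", (18, 19), 35),
        ("additive", "nonparametric", (3, 3), 4),
        ("saturated", "nonparametric", (18, 19), 341),
        ("saturated", "nonparametric", (3, 3), 8),
        ("additive", "parametric", (3, 3), 2),
        ("additive_plus_congruence", "parametric", (3, 3), 3),
        ("additive_plus_both", "parametric", (3, 3), 4),
    ],
)
def test_design_matrix_column_counts(structure, form, grid_size, n_cols):
    grid = build_grid(*grid_size)
    design = exhaustive_design(grid)
    dm = encode_trials(design.trials, grid, ModelSpec(structure, form))
    assert dm.shape == (len(design.trials), n_cols)


def test_interaction_structures_require_parametric_form():
    with pytest.raises(ValueError):
        ModelSpec("additive_plus_congruence", "nonparametric")
    with pytest.raises(ValueError):
        ModelSpec("no_such_structure", "parametric")


def test_nonparametric_rows_are_signed_indicators(grid3):
    trials = pd.DataFrame(
        {"face1": [2], "voice1": [0], "face2": [1], "voice2": [0]}
    )
    dm = encode_trials(trials, grid3, ModelSpec("additive", "nonparametric"))
    # columns: face_1, face_2, voice_1, voice_2
    assert dm.columns == ["face_1", "face_2", "voice_1", "voice_2"]
    np.testing.assert_allclose(dm.X[0], [-1.0, 1.0, 0.0, 0.0])


def test_parametric_recovery_within_tolerance(design3x50, grid3):
    """Pooled probit MLE recovers (beta_v, beta_a) within +-0.15."""
    params = ObserverParams(beta_v=2.0, beta_a=1.0)
    rs = simulate_responses(design3x50, params, rng=np.random.default_rng(12345))
    dm = encode_trials(rs.data, grid3, ModelSpec("additive", "parametric"))
    fit = fit_mlcm(dm, rs.data["response"])
    assert fit.converged
    assert fit.estimates["beta_v"] == pytest.approx(2.0, abs=0.15)
    assert fit.estimates["beta_a"] == pytest.approx(1.0, abs=0.15)
    assert fit.loglik <= 0
    assert fit.aic == pytest.approx(2 * 2 - 2 * fit.loglik)


def test_mle_agrees_with_direct_grid_optimization(design3x50, grid3):
    """The GLM solution matches a brute-force probit likelihood optimum."""
    rs = simulate_responses(
        design3x50, ObserverParams(beta_v=1.5, beta_a=0.8),
        rng=np.random.default_rng(777),
    )
    dm = encode_trials(rs.data, grid3, ModelSpec("additive", "parametric"))
    y = rs.data["response"].to_numpy()
    fit = fit_mlcm(dm, y)

    def nll(beta):
        eta = dm.X @ beta
        s = 2 * y - 1.0
        return -norm.logcdf(s * eta).sum()

    brute = minimize(nll, np.zeros(2), method="Nelder-Mead",
                     options={"xatol": 1e-8, "fatol": 1e-10})
    np.testing.assert_allclose(fit.estimates.to_numpy(), brute.x, atol=1e-3)
    assert fit.loglik == pytest.approx(-brute.fun, abs=1e-4)


def test_loglik_nests_across_model_ladder(design3x50, grid3):
    rs = simulate_responses(
        design3x50,
        ObserverParams(beta_v=1.2, beta_a=0.9, theta_cong=0.5, theta_mag=0.4),
        rng=np.random.default_rng(5),
    )
    y = rs.data["response"]
    ladder = ["independence_v", "additive", "additive_plus_congruence",
              "additive_plus_both"]
    lls = []
    for structure in ladder:
        dm = encode_trials(rs.data, grid3, ModelSpec(structure, "parametric"))
        lls.append(fit_mlcm(dm, y).loglik)
    assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))


def test_nonparametric_anchoring_and_scale_recovery(grid3):
    """Anchored level is 0; fitted scale tracks the generating d-prime scale."""
    design = exhaustive_design(grid3, n_repeats=200)
    params = ObserverParams(beta_v=2.0, beta_a=1.0)
    rs = simulate_responses(design, params, rng=np.random.default_rng(21))
    dm = encode_trials(rs.data, grid3, ModelSpec("additive", "nonparametric"))
    fit = fit_mlcm(dm, rs.data["response"])
    face = fit.scale_values("face")
    voice = fit.scale_values("voice")
    assert face[0] == 0.0 and voice[0] == 0.0
    np.testing.assert_allclose(face, 2.0 * grid3.face_coords**2, atol=0.25)
    np.testing.assert_allclose(voice, 1.0 * grid3.voice_coords, atol=0.25)


def test_degenerate_and_pathological_inputs(grid3):
    same = pd.DataFrame({"face1": [1] * 4, "voice1": [1] * 4,
                         "face2": [1] * 4, "voice2": [1] * 4})
    dm = encode_trials(same, grid3, ModelSpec("additive", "parametric"))
    with pytest.raises(ValueError, match="no information"):
        fit_mlcm(dm, np.array([0, 1, 0, 1]))
    trials = pd.DataFrame({"face1": [2, 0], "voice1": [0, 0],
                           "face2": [0, 2], "voice2": [0, 0]})
    dm = encode_trials(trials, grid3, ModelSpec("additive", "parametric"))
    with pytest.raises(ValueError, match="binary"):
        fit_mlcm(dm, np.array([0, 2]))
    with pytest.raises(ValueError, match="bounds"):
        encode_trials(pd.DataFrame({"face1": [5], "voice1": [0],
                                    "face2": [0], "voice2": [0]}),
                      grid3, ModelSpec("additive", "parametric"))


def test_separation_flagged_not_fatal(grid3):
    """A perfectly consistent observer yields unbounded estimates, flagged."""
    design = exhaustive_design(grid3, n_repeats=3)
    rs = simulate_responses(design, ObserverParams(beta_v=5.0, beta_a=2.0, sigma=0.0))
    keep = rs.data[
        (rs.data[["face1", "voice1"]].to_numpy()
         != rs.data[["face2", "voice2"]].to_numpy()).any(axis=1)
    ]
    dm = encode_trials(keep, grid3, ModelSpec("additive", "parametric"))
    fit = fit_mlcm(dm, keep["response"])
    assert not fit.converged
    assert fit.diagnostic != ""


def test_collinear_columns_named(grid3):
    trials = pd.DataFrame({"face1": [1, 2], "voice1": [1, 2],
                           "face2": [0, 0], "voice2": [0, 0]})
    dm = encode_trials(trials, grid3, ModelSpec("additive", "nonparametric"))
    with pytest.raises(ValueError, match="collinear"):
        fit_mlcm(dm, np.array([1, 0]))


def test_scale_shape_fit_recovers_amplitudes(grid3):
    """Exact quadratic/linear scales give zero residual and the true amplitude."""
    design = exhaustive_design(grid3, n_repeats=150)
    rs = simulate_responses(design, ObserverParams(beta_v=2.5, beta_a=1.5),
                            rng=np.random.default_rng(3))
    dm = encode_trials(rs.data, grid3, ModelSpec("additive", "nonparametric"))
    fit = fit_mlcm(dm, rs.data["response"])
    res = fit_scale_shapes({"face": fit})
    amp = res["amplitudes"]["face"]
    assert amp["face"] == pytest.approx(2.5, abs=0.4)
    assert amp["voice"] == pytest.approx(1.5, abs=0.4)
    # shape correlation with the quadratic form
    sv = fit.scale_values("face")
    assert np.corrcoef(sv, grid3.face_coords**2)[0, 1] > 0.98

    # synthetic exact-scale fit: residual 0, amplitude c
    exact = fit_scale_shapes(
        {
            "t": type(fit)(
                fit.spec, fit.grid,
                pd.Series(
                    np.concatenate(
                        [3.0 * grid3.face_coords[1:] ** 2, 0.0 * grid3.voice_coords[1:]]
                    ),
                    index=fit.estimates.index,
                ),
                fit.se, 0.0, fit.n_params, True,
            )
        }
    )
    assert exact["amplitudes"]["t"]["face"] == pytest.approx(3.0)
    assert exact["rss"]["t"]["face"] == pytest.approx(0.0, abs=1e-20)
    assert exact["amplitudes"]["t"]["voice"] == pytest.approx(0.0)


def test_predict_choice_consistency(design3x50, grid3):
    params = ObserverParams(beta_v=1.0, beta_a=0.7, theta_mag=0.3)
    rs = simulate_responses(design3x50, params, rng=np.random.default_rng(8))
    dm = encode_trials(rs.data, grid3, ModelSpec("additive_plus_both", "parametric"))
    fit = fit_mlcm(dm, rs.data["response"])
    assert predict_choice(fit, (((1, 1), (1, 1)))) == pytest.approx(0.5)

    dm_add = encode_trials(rs.data, grid3, ModelSpec("additive", "parametric"))
    fit_add = fit_mlcm(dm_add, rs.data["response"])
    p = predict_choice(fit_add, ((2, 0), (0, 1)))
    q = predict_choice(fit_add, ((0, 1), (2, 0)))
    assert p + q == pytest.approx(1.0, abs=1e-10)

    # with coefficients forced to the generating values, prediction equals
    # the generative choice probability
    from facevoice.observers import choice_probability

    forced = type(fit)(
        fit.spec, fit.grid,
        pd.Series({"beta_v": 1.0, "beta_a": 0.7, "theta_cong": 0.0, "theta_mag": 0.3}),
        fit.se, fit.cov, fit.loglik, fit.n_params, True,
    )
    for pair in [((2, 0), (0, 1)), ((1, 2), (2, 1))]:
        assert predict_choice(forced, pair) == pytest.approx(
            choice_probability(grid3, pair, params), abs=1e-12
        )
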