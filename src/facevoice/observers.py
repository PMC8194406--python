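"""Synthetic observers for paired gender comparisons.

Binary judgments follow a signal-detection decision model: each stimulus
(face morph phi_V, voice morph phi_A) evokes internal gender responses
through fixed modality shapes (quadratic for the face, linear for the
voice), and the decision variable for a pair is

    delta = beta_v * (g_V(phi1V) - g_V(phi2V))
          + beta_a * (g_A(phi1A) - g_A(phi2A))
          + theta_cong * (|g_V(phi1V) - g_A(phi1A)| - |g_V(phi2V) - g_A(phi2A)|)
          + theta_mag  * (g_V(phi1V) - g_V(phi2V)) * (g_A(phi1A) - g_A(phi2A))

with standard-normal judgment noise added; the observer chooses the first
stimulus whenever the noisy decision variable is positive.  Setting both
theta terms to zero gives the additive model, and additionally zeroing one
beta gives an independence model.  The congruence regressor is the
difference of the two within-stimulus absolute face-voice discrepancies,
which keeps the decision variable antisymmetric under exchange of the two
stimuli.

A reliability-weighted (precision-weighted) cue-fusion account of the two
interaction effects is also provided: congruence inflates each unimodal
variance in proportion to the cross-modal discrepancy, and gender
magnitude sharpens it with distance from the gender-neutral point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import MorphGrid, TrialDesign, sample_design

__all__ = [
    "GenderShape",
    "VISUAL_SHAPE",
    "AUDITORY_SHAPE",
    "ObserverParams",
    "FusionComponents",
    "ResponseSet",
    "CohortConfig",
    "TASK_DEFAULTS",
    "gender_value",
    "decision_value",
    "choice_probability",
    "simulate_responses",
    "fuse_estimates",
    "interaction_variances",
    "masculine_probability",
    "simulate_cohort",
]


@dataclass(frozen=True)
class GenderShape:
    """Normalized mapping from morph coordinate to internal gender value.

    Both forms satisfy g(0) = 0, g(1) = 1 and are monotone on [0, 1].
    """

    form: str  # 'linear' or 'quadratic'

    def __post_init__(self):
        if self.form not in ("linear", "quadratic"):
            raise ValueError(f"unknown shape form {self.form!r}")

    def __call__(self, phi):
        phi = np.asarray(phi, dtype=float)
        if np.any(phi < 0) or np.any(phi > 1):
            raise ValueError("morph coordinate must lie in [0, 1]")
        return phi**2 if self.form == "quadratic" else phi + 0.0


#: Face contribution: quadratic in morph level.
VISUAL_SHAPE = GenderShape("quadratic")
#: Voice contribution: linear in morph level.
AUDITORY_SHAPE = GenderShape("linear")


def gender_value(shape: GenderShape, phi: float) -> float:
    """Evaluate a normalized gender shape at morph coordinate ``phi``."""
    return float(shape(phi))


@dataclass(frozen=True)
class ObserverParams:
    """Generative decision-model parameters for one synthetic observer.

    Weights are in d-prime units of a full-range morph change; ``sigma``
    is the judgment-noise SD (1 by definition of the d-prime scale;
    0 selects the deterministic noiseless mode in simulation).
    """

    task: str = "stimulus"
    beta_v: float = 1.0
    beta_a: float = 1.0
    theta_cong: float = 0.0
    theta_mag: float = 0.0
    sigma: float = 1.0
    seed: int | None = None
    shape_v: GenderShape = VISUAL_SHAPE
    shape_a: GenderShape = AUDITORY_SHAPE

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def _pair_regressors(grid: MorphGrid, trials: pd.DataFrame, params: ObserverParams):
    """Per-trial regressors (dv, da, dcong, dmag) for ordered pairs."""
    gv1 = params.shape_v(grid.face_coords[trials["face1"].to_numpy()])
    gv2 = params.shape_v(grid.face_coords[trials["face2"].to_numpy()])
    ga1 = params.shape_a(grid.voice_coords[trials["voice1"].to_numpy()])
    ga2 = params.shape_a(grid.voice_coords[trials["voice2"].to_numpy()])
    dv = gv1 - gv2
    da = ga1 - ga2
    dcong = np.abs(gv1 - ga1) - np.abs(gv2 - ga2)
    dmag = dv * da
    return dv, da, dcong, dmag


def _decision_values(grid, trials, params) -> np.ndarray:
    dv, da, dcong, dmag = _pair_regressors(grid, trials, params)
    return (
        params.beta_v * dv
        + params.beta_a * da
        + params.theta_cong * dcong
        + params.theta_mag * dmag
    )


def _pair_frame(pair) -> pd.DataFrame:
    (f1, v1), (f2, v2) = pair
    return pd.DataFrame(
        {"face1": [f1], "voice1": [v1], "face2": [f2], "voice2": [v2]}
    )


def decision_value(grid: MorphGrid, pair, params: ObserverParams) -> float:
    """Noiseless decision value for an ordered pair of (face, voice) levels."""
    return float(_decision_values(grid, _pair_frame(pair), params)[0])


def choice_probability(grid: MorphGrid, pair, params: ObserverParams) -> float:
    """Probability of choosing the first stimulus: Phi(delta / sigma)."""
    if params.sigma <= 0:
        raise ValueError("choice_probability requires sigma > 0")
    return float(norm.cdf(decision_value(grid, pair, params) / params.sigma))


@dataclass(frozen=True)
class ResponseSet:
    """Simulated responses for one observer: design plus binary choices.

    ``data`` is the design trial table with a ``response`` column
    (1 = chose the first stimulus).
    """

    design: TrialDesign
    data: pd.DataFrame = field(repr=False)
    observer_id: str = "obs0"
    task: str = "stimulus"


def simulate_responses(
    design: TrialDesign,
    params: ObserverParams,
    observer_id: str = "obs0",
    rng: np.random.Generator | None = None,
) -> ResponseSet:
    """Draw one binary response per trial under the decision model.

    With ``sigma == 0`` responses are deterministic: 1 where delta > 0,
    otherwise 0 (ties included).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    delta = _decision_values(design.grid, design.trials, params)
    if params.sigma == 0:
        resp = (delta > 0).astype(int)
    else:
        eps = rng.normal(0.0, params.sigma, size=len(delta))
        resp = (delta + eps > 0).astype(int)
    data = design.trials.copy()
    data["response"] = resp
    return ResponseSet(design, data, observer_id, params.task)


# ---------------------------------------------------------------------------
# Reliability-weighted cue fusion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FusionComponents:
    """Unimodal perceived-gender distributions and interaction gains."""

    mu_v: float
    sigma_v: float
    mu_a: float
    sigma_a: float
    kappa_cong: float = 0.0
    kappa_mag: float = 0.0

    def __post_init__(self):
        if self.sigma_v <= 0 or self.sigma_a <= 0:
            raise ValueError("unimodal SDs must be > 0")
        if self.kappa_cong < 0 or self.kappa_mag < 0:
            raise ValueError("interaction gains must be >= 0")


def fuse_estimates(fc: FusionComponents) -> tuple[float, float]:
    """Precision-weighted fusion of the two unimodal estimates.

    Returns (fused mean, fused SD); the fused variance
    1 / (sigma_v^-2 + sigma_a^-2) never exceeds either unimodal variance.
    """
    wv, wa = fc.sigma_v**-2, fc.sigma_a**-2
    mean = (fc.mu_v * wv + fc.mu_a * wa) / (wv + wa)
    var = 1.0 / (wv + wa)
    return float(mean), float(np.sqrt(var))


def interaction_variances(fc: FusionComponents) -> tuple[float, float]:
    """Adjusted unimodal SDs before fusion.

    Congruence: each SD is inflated in proportion to the cross-modal
    discrepancy, sigma * (1 + kappa_cong * |mu_v - mu_a|).  Magnitude:
    each SD shrinks with that modality's distance from the gender-neutral
    midpoint, sigma / (1 + kappa_mag * |mu - 1/2|).
    """
    disc = abs(fc.mu_v - fc.mu_a)
    sv = fc.sigma_v * (1.0 + fc.kappa_cong * disc)
    sa = fc.sigma_a * (1.0 + fc.kappa_cong * disc)
    sv = sv / (1.0 + fc.kappa_mag * abs(fc.mu_v - 0.5))
    sa = sa / (1.0 + fc.kappa_mag * abs(fc.mu_a - 0.5))
    return float(sv), float(sa)


def masculine_probability(fc: FusionComponents, neutral: float = 0.5) -> float:
    """Probability the fused percept is classified masculine (above neutral)."""
    sv, sa = interaction_variances(fc)
    mean, sd = fuse_estimates(replace(fc, sigma_v=sv, sigma_a=sa))
    return float(norm.cdf((mean - neutral) / sd))


# ---------------------------------------------------------------------------
# Cohort simulation (study-shaped synthetic data)
# ---------------------------------------------------------------------------

#: Per-task mean weights reproducing the study's qualitative weight pattern:
#: roughly 5x face dominance in the face task, 8x voice dominance in the
#: voice task (hence a ~40-fold ratio-of-ratios across tasks), and near
#: equality in the stimulus task.
TASK_DEFAULTS = {
    "face": {"beta_v": 3.5, "beta_a": 0.7},
    "voice": {"beta_v": 0.6, "beta_a": 4.8},
    "stimulus": {"beta_v": 2.0, "beta_a": 2.0},
}


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a simulated multi-observer study arm (one task)."""

    task: str = "stimulus"
    n_observers: int = 12
    n_trials: int = 1500
    n_sessions: int = 5
    beta_v: float | None = None  # None -> TASK_DEFAULTS[task]
    beta_a: float | None = None
    theta_cong: float = 0.0
    theta_mag: float = 0.0
    sd_beta_v: float = 0.5
    sd_beta_a: float = 0.5

    def mean_params(self) -> tuple[float, float]:
        d = TASK_DEFAULTS[self.task]
        bv = d["beta_v"] if self.beta_v is None else self.beta_v
        ba = d["beta_a"] if self.beta_a is None else self.beta_a
        return bv, ba


def simulate_cohort(
    grid: MorphGrid,
    config: CohortConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a study-shaped cohort for one task.

    Each observer gets an independently subsampled design and weights
    drawn from uncorrelated normal between-observer distributions on
    (beta_v, beta_a); interaction coefficients are shared.  Observer sex
    and judgment direction (masculine/feminine) are assigned in balanced
    alternation as inert metadata for group-factor tests.

    Returns ``(trials, observers)``: a long trial table with one row per
    response and a per-observer parameter table.
    """
    rng = np.random.default_rng(seed)
    bv0, ba0 = config.mean_params()
    trial_frames, obs_rows = [], []
    for i in range(config.n_observers):
        bv = rng.normal(bv0, config.sd_beta_v)
        ba = rng.normal(ba0, config.sd_beta_a)
        params = ObserverParams(
            task=config.task,
            beta_v=bv,
            beta_a=ba,
            theta_cong=config.theta_cong,
            theta_mag=config.theta_mag,
        )
        design = sample_design(
            grid,
            config.n_trials,
            config.n_sessions,
            seed=int(rng.integers(2**31)),
        )
        rs = simulate_responses(design, params, observer_id=f"obs{i:02d}", rng=rng)
        df = rs.data.copy()
        df.insert(0, "observer_id", rs.observer_id)
        df.insert(1, "task", config.task)
        trial_frames.append(df)
        obs_rows.append(
            {
                "observer_id": rs.observer_id,
                "task": config.task,
                "sex": ("male", "female")[i % 2],
                "direction": ("masculine", "feminine")[(i // 2) % 2],
                "beta_v": bv,
                "beta_a": ba,
                "theta_cong": config.theta_cong,
                "theta_mag": config.theta_mag,
            }
        )
    return pd.concat(trial_frames, ignore_index=True), pd.DataFrame(obs_rows)
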