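"""Maximum likelihood conjoint measurement (MLCM) by probit binomial GLM.

Paired-comparison responses are modeled as Bernoulli draws with
P(choose first) = Phi(delta), where delta is linear in either

* nonparametric per-level scale values (one d-prime value per morph
  level, the most feminine level of each modality anchored at 0 and the
  judgment-noise SD fixed at 1 for identifiability), or
* a handful of parametric coefficients weighting fixed modality shapes
  (quadratic face, linear voice) plus optional congruence and magnitude
  interaction regressors.

The trial design matrix carries signed differences between the two
stimuli of each pair, so the whole problem is an ordinary binomial GLM
with a probit link and no intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import MorphGrid
from .observers import AUDITORY_SHAPE, VISUAL_SHAPE, GenderShape

from scipy import linalg
from scipy.stats import norm

__all__ = [
    "ModelSpec",
    "DesignMatrix",
    "ScaleFit",
    "ParametricFit",
    "encode_trials",
    "fit_mlcm",
    "fit_scale_shapes",
    "predict_choice",
    "PARAMETRIC_COLUMNS",
]

NONPARAMETRIC_STRUCTURES = ("independence_v", "independence_a", "additive", "saturated")
PARAMETRIC_STRUCTURES = (
    "independence_v",
    "independence_a",
    "additive",
    "additive_plus_congruence",
    "additive_plus_magnitude",
    "additive_plus_both",
)

#: Coefficient columns used by each parametric structure.
PARAMETRIC_COLUMNS = {
    "independence_v": ["beta_v"],
    "independence_a": ["beta_a"],
    "additive": ["beta_v", "beta_a"],
    "additive_plus_congruence": ["beta_v", "beta_a", "theta_cong"],
    "additive_plus_magnitude": ["beta_v", "beta_a", "theta_mag"],
    "additive_plus_both": ["beta_v", "beta_a", "theta_cong", "theta_mag"],
}

#: Estimates beyond this magnitude (d-prime units) are treated as separation.
SEPARATION_BOUND = 50.0


@dataclass(frozen=True)
class ModelSpec:
    """Which decision-rule structure to fit, and in which form.

    Interaction structures are only available in parametric form,
    matching the parametric-reduction workflow (fixed curve shapes,
    free amplitude coefficients).
    """

    structure: str = "additive"
    form: str = "nonparametric"
    shape_v: GenderShape = VISUAL_SHAPE
    shape_a: GenderShape = AUDITORY_SHAPE

    def __post_init__(self):
        if self.form not in ("nonparametric", "parametric"):
            raise ValueError(f"unknown form {self.form!r}")
        allowed = (
            PARAMETRIC_STRUCTURES if self.form == "parametric" else NONPARAMETRIC_STRUCTURES
        )
        if self.structure not in allowed:
            raise ValueError(
                f"structure {self.structure!r} not available in {self.form} form"
            )


@dataclass(frozen=True)
class DesignMatrix:
    """Trial-difference design matrix with labeled columns."""

    X: np.ndarray = field(repr=False)
    columns: list[str]
    spec: ModelSpec
    grid: MorphGrid

    @property
    def shape(self):
        return self.X.shape


def _level_diff_block(levels1, levels2, n_levels, prefix) -> tuple[np.ndarray, list[str]]:
    """Signed +1/-1 indicator differences, anchor level 0 omitted."""
    n = len(levels1)
    X = np.zeros((n, n_levels - 1))
    rows = np.arange(n)
    m1 = levels1 > 0
    X[rows[m1], levels1[m1] - 1] += 1.0
    m2 = levels2 > 0
    X[rows[m2], levels2[m2] - 1] -= 1.0
    cols = [f"{prefix}{k}" for k in range(1, n_levels)]
    return X, cols


def encode_trials(trials: pd.DataFrame, grid: MorphGrid, spec: ModelSpec) -> DesignMatrix:
    """Build the model's trial-difference design matrix.

    ``trials`` needs columns face1, voice1, face2, voice2 (0-based level
    indices).  Nonparametric blocks carry per-level indicator
    differences; parametric columns carry shape differences and the
    interaction regressors of the generative decision model.
    """
    f1 = trials["face1"].to_numpy(int)
    f2 = trials["face2"].to_numpy(int)
    v1 = trials["voice1"].to_numpy(int)
    v2 = trials["voice2"].to_numpy(int)
    for arr, n in ((f1, grid.n_face), (f2, grid.n_face), (v1, grid.n_voice), (v2, grid.n_voice)):
        if arr.min(initial=0) < 0 or arr.max(initial=0) >= n:
            raise ValueError("trial levels outside grid bounds")

    if spec.form == "nonparametric":
        blocks, cols = [], []
        if spec.structure in ("independence_v", "additive"):
            X, c = _level_diff_block(f1, f2, grid.n_face, "face_")
            blocks.append(X)
            cols += c
        if spec.structure in ("independence_a", "additive"):
            X, c = _level_diff_block(v1, v2, grid.n_voice, "voice_")
            blocks.append(X)
            cols += c
        if spec.structure == "saturated":
            # one term per grid cell, anchor cell (0, 0) omitted
            cell1 = f1 * grid.n_voice + v1
            cell2 = f2 * grid.n_voice + v2
            X, c = _level_diff_block(cell1, cell2, grid.n_stimuli, "cell_")
            blocks.append(X)
            cols = c
        return DesignMatrix(np.hstack(blocks), cols, spec, grid)

    gv1 = spec.shape_v(grid.face_coords[f1])
    gv2 = spec.shape_v(grid.face_coords[f2])
    ga1 = spec.shape_a(grid.voice_coords[v1])
    ga2 = spec.shape_a(grid.voice_coords[v2])
    regs = {
        "beta_v": gv1 - gv2,
        "beta_a": ga1 - ga2,
        "theta_cong": np.abs(gv1 - ga1) - np.abs(gv2 - ga2),
        "theta_mag": (gv1 - gv2) * (ga1 - ga2),
    }
    cols = PARAMETRIC_COLUMNS[spec.structure]
    X = np.column_stack([regs[c] for c in cols])
    return DesignMatrix(X, cols, spec, grid)


@dataclass(frozen=True)
class ScaleFit:
    """Nonparametric MLCM fit: per-level d-prime estimates."""

    spec: ModelSpec
    grid: MorphGrid
    estimates: pd.Series = field(repr=False)  # indexed by column label
    se: pd.Series = field(repr=False)
    loglik: float
    n_params: int
    converged: bool
    diagnostic: str = ""

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik

    def scale_values(self, modality: str) -> np.ndarray:
        """Full per-level scale (anchor level prepended as exactly 0)."""
        prefix = {"face": "face_", "voice": "voice_"}[modality]
        vals = [v for k, v in self.estimates.items() if k.startswith(prefix)]
        return np.concatenate([[0.0], vals])


@dataclass(frozen=True)
class ParametricFit:
    """Parametric MLCM fit: shape-amplitude and interaction coefficients."""

    spec: ModelSpec
    grid: MorphGrid
    estimates: pd.Series = field(repr=False)
    se: pd.Series = field(repr=False)
    cov: pd.DataFrame = field(repr=False)
    loglik: float
    n_params: int
    converged: bool
    diagnostic: str = ""

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik

    def coef(self, name: str) -> float:
        """Coefficient value; structurally absent coefficients are 0."""
        return float(self.estimates.get(name, 0.0))


def _check_rank(dm: DesignMatrix):
    X = dm.X
    if not np.any(X):
        raise ValueError("design matrix is all zero: trials carry no information")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns involved in collinearity via QR pivoting
        _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
        bad = [dm.columns[i] for i in piv[rank:]]
        raise ValueError(f"rank-deficient design matrix; collinear columns: {bad}")


def fit_mlcm(dm: DesignMatrix, responses) -> ScaleFit | ParametricFit:
    """Fit the probit MLCM model by maximum likelihood.

    ``responses`` is a binary array (1 = chose first stimulus), one per
    design-matrix row.  Complete separation is reported through the
    ``converged`` flag with a diagnostic rather than raised.
    """
    y = np.asarray(responses, dtype=float)
    if y.shape[0] != dm.X.shape[0]:
        raise ValueError("responses and design matrix disagree in length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("responses must be binary")
    _check_rank(dm)

    model = sm.GLM(y, dm.X, family=sm.families.Binomial(sm.families.links.Probit()))
    converged, diagnostic = True, ""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=200, tol=1e-10)
            params = res.params
            bse = res.bse
            cov = res.cov_params()
            llf = float(res.llf)
        if not np.all(np.isfinite(params)) or np.abs(params).max() > SEPARATION_BOUND:
            converged = False
            diagnostic = "estimates unbounded: complete or quasi-complete separation"
    except Exception as exc:  # statsmodels raises on exact separation
        converged = False
        diagnostic = f"separation / optimizer failure: {exc}"
        params = np.full(dm.X.shape[1], np.nan)
        bse = np.full(dm.X.shape[1], np.nan)
        cov = np.full((dm.X.shape[1],) * 2, np.nan)
        llf = np.nan

    est = pd.Series(params, index=dm.columns)
    se = pd.Series(bse, index=dm.columns)
    k = dm.X.shape[1]
    if dm.spec.form == "parametric":
        return ParametricFit(
            dm.spec,
            dm.grid,
            est,
            se,
            pd.DataFrame(cov, index=dm.columns, columns=dm.columns),
            llf,
            k,
            converged,
            diagnostic,
        )
    return ScaleFit(dm.spec, dm.grid, est, se, llf, k, converged, diagnostic)


def fit_scale_shapes(
    scale_fits: dict[str, ScaleFit],
) -> dict[str, object]:
    """Fit fixed curve shapes to nonparametric scale estimates.

    Least-squares fit of an amplitude-scaled quadratic to the face scale
    and an amplitude-scaled linear function to the voice scale of each
    task's fit; shapes are shared across tasks, amplitudes free per task.
    Returns the shapes, per-task amplitudes and residual sums of squares.
    """
    if not scale_fits:
        raise ValueError("no fits supplied")
    amplitudes, rss = {}, {}
    for task, fit in scale_fits.items():
        if fit.grid.n_face < 2 or fit.grid.n_voice < 2:
            raise ValueError("need at least 2 levels per modality to fit a shape")
        gv = VISUAL_SHAPE(fit.grid.face_coords)
        ga = AUDITORY_SHAPE(fit.grid.voice_coords)
        sv = fit.scale_values("face")
        sa = fit.scale_values("voice")
        av = float(gv @ sv / (gv @ gv))
        aa = float(ga @ sa / (ga @ ga))
        amplitudes[task] = {"face": av, "voice": aa}
        rss[task] = {
            "face": float(np.sum((sv - av * gv) ** 2)),
            "voice": float(np.sum((sa - aa * ga) ** 2)),
        }
    return {
        "shape_v": VISUAL_SHAPE,
        "shape_a": AUDITORY_SHAPE,
        "amplitudes": amplitudes,
        "rss": rss,
    }


def predict_choice(fit: ScaleFit | ParametricFit, pair) -> float:
    """Predicted probability of choosing the first stimulus of ``pair``."""
    if not fit.converged or not np.all(np.isfinite(fit.estimates)):
        raise RuntimeError("cannot predict from a non-converged fit")
    (f1, v1), (f2, v2) = pair
    grid = fit.grid
    if isinstance(fit, ParametricFit):
        gv1, gv2 = fit.spec.shape_v(grid.face_coords[[f1, f2]])
        ga1, ga2 = fit.spec.shape_a(grid.voice_coords[[v1, v2]])
        delta = (
            fit.coef("beta_v") * (gv1 - gv2)
            + fit.coef("beta_a") * (ga1 - ga2)
            + fit.coef("theta_cong") * (abs(gv1 - ga1) - abs(gv2 - ga2))
            + fit.coef("theta_mag") * (gv1 - gv2) * (ga1 - ga2)
        )
    else:
        delta = 0.0
        if fit.spec.structure in ("independence_v", "additive"):
            s = fit.scale_values("face")
            delta += s[f1] - s[f2]
        if fit.spec.structure in ("independence_a", "additive"):
            s = fit.scale_values("voice")
            delta += s[v1] - s[v2]
        if fit.spec.structure == "saturated":
            vals = np.concatenate([[0.0], fit.estimates.to_numpy()])
            delta = vals[f1 * grid.n_voice + v1] - vals[f2 * grid.n_voice + v2]
    return float(norm.cdf(delta))
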