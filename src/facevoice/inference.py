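"""Multi-observer inference: probit GLMM, nested tests, model ladder.

The cohort model extends the probit MLCM decision model with per-observer
random slopes on the modality regressors: for observer s,

    P(choose first) = Phi(x_i' beta + z_i' b_s),   b_s ~ N(0, diag(sigma^2))

where beta are fixed coefficients shared across observers and b_s are
independent normal deviations on the visual and/or auditory weight.
The marginal likelihood integrates the random slopes out; we use a
per-observer Laplace approximation (Newton mode finding on the joint
log density, then a Gaussian integral around the mode), which is exact
in the Gaussian limit and accurate here because each observer
contributes hundreds to thousands of trials.

Model comparison follows a fixed ladder of nested likelihood-ratio
tests: judgment-direction and observer-sex group factors (each as a
2-df fixed interaction with the modality regressors), independence vs
additive (2 df: one fixed weight plus one variance component), and the
additive model vs each 1-df interaction extension (gender magnitude,
gender congruence).  dAIC is reported as AIC_nested - AIC_full =
chisq - 2 df, so positive values favor the fuller model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2, norm

from .design import MorphGrid
from .scales import ModelSpec, encode_trials, fit_mlcm

__all__ = [
    "GLMMFit",
    "ComparisonRow",
    "ComparisonTable",
    "fit_glmm",
    "lrt",
    "model_ladder",
    "predictive_accuracy",
]

_INNER_TOL = 1e-8
_OUTER_TOL = 1e-6
_LOG_SD_BOUNDS = (np.log(1e-4), np.log(10.0))
_SINGULAR_SD = 1e-3

_LADDER_BLOCKS = (
    "masculine/feminine",
    "male/female",
    "independence/additive",
    "additive/gender interaction",
    "additive/congruence interaction",
)


@dataclass(frozen=True)
class GLMMFit:
    """Laplace-approximate ML fit of the probit random-slopes model."""

    spec: ModelSpec
    grid: MorphGrid
    fixed: pd.Series = field(repr=False)  # fixed coefficients by column label
    sd_re: pd.Series = field(repr=False)  # random-slope SDs by column label
    ranef: pd.DataFrame = field(repr=False)  # observers x slopes, mode predictions
    loglik: float
    n_params: int  # fixed + variance components
    converged: bool
    singular: bool
    group_factor: str | None = None

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik


def _probit_parts(eta: np.ndarray, y: np.ndarray):
    """Log-likelihood, working residual and weight of the probit model."""
    s = 2.0 * y - 1.0
    t = s * eta
    logcdf = norm.logcdf(t)
    r = np.exp(norm.logpdf(t) - logcdf)  # inverse Mills ratio, stable
    ll = float(logcdf.sum())
    grad_eta = s * r
    w = r * (t + r)  # -d2 loglik / d eta2, nonnegative
    return ll, grad_eta, w


def _laplace_observer(X, y, Z, beta, sd, b0):
    """Laplace-approximate marginal log-likelihood for one observer.

    Returns (loglik, mode).  ``Z`` is the slice of X columns carrying
    random slopes; ``sd`` their SD vector; ``b0`` a warm-start mode.
    """
    q = Z.shape[1]
    prec = 1.0 / sd**2
    xb = X @ beta
    b = b0.copy()
    for _ in range(50):
        ll, g_eta, w = _probit_parts(xb + Z @ b, y)
        grad = Z.T @ g_eta - prec * b
        H = Z.T @ (w[:, None] * Z) + np.diag(prec)
        step = np.linalg.solve(H, grad)
        # step-halving on the penalized objective
        h0 = ll - 0.5 * np.sum(prec * b**2)
        alpha = 1.0
        for _ in range(20):
            b_new = b + alpha * step
            ll_new, _, _ = _probit_parts(xb + Z @ b_new, y)
            if ll_new - 0.5 * np.sum(prec * b_new**2) >= h0 - 1e-12:
                break
            alpha *= 0.5
        b = b + alpha * step
        if np.max(np.abs(grad)) < _INNER_TOL:
            break
    ll, _, w = _probit_parts(xb + Z @ b, y)
    h = ll - 0.5 * np.sum(prec * b**2)
    H = Z.T @ (w[:, None] * Z) + np.diag(prec)
    _, logdet_h = np.linalg.slogdet(H)
    logdet_d = 2.0 * np.sum(np.log(sd))
    return h - 0.5 * logdet_d - 0.5 * logdet_h, b


def _group_codes(observers: pd.DataFrame, factor: str) -> pd.Series:
    levels = sorted(observers[factor].unique())
    if len(levels) != 2:
        raise ValueError(f"group factor {factor!r} must have exactly 2 levels")
    return observers.set_index("observer_id")[factor].map(
        {levels[0]: -0.5, levels[1]: 0.5}
    )


def fit_glmm(
    trials: pd.DataFrame,
    grid: MorphGrid,
    spec: ModelSpec,
    observers: pd.DataFrame | None = None,
    group_factor: str | None = None,
    random_slopes: tuple[str, ...] | None = None,
) -> GLMMFit:
    """Fit the probit random-slopes model to a cohort trial table.

    ``trials`` needs observer_id, face1..voice2 and response columns.
    Random slopes default to the modality regressors present in the
    model (never the interaction coefficients).  ``group_factor`` adds
    centered group x modality fixed interactions (2 df) for the
    group-difference tests; it requires the ``observers`` table.
    """
    if spec.form != "parametric":
        raise ValueError("cohort models use the parametric form")
    obs_ids = trials["observer_id"].unique()
    if len(obs_ids) < 2:
        raise ValueError(
            "need >= 2 observers for a mixed model; use scales.fit_mlcm for one"
        )
    dm = encode_trials(trials, grid, spec)
    columns = list(dm.columns)
    modality_cols = [c for c in columns if c in ("beta_v", "beta_a")]
    if random_slopes is None:
        random_slopes = tuple(modality_cols)
    if any(c not in modality_cols for c in random_slopes):
        raise ValueError("random slopes are restricted to the modality regressors")

    X = dm.X
    if group_factor is not None:
        if observers is None:
            raise ValueError("group_factor requires the observers table")
        codes = _group_codes(observers, group_factor)
        g = trials["observer_id"].map(codes).to_numpy(float)
        for c in modality_cols:
            X = np.column_stack([X, g * dm.X[:, columns.index(c)]])
        columns = columns + [f"{group_factor}:{c}" for c in modality_cols]

    y = trials["response"].to_numpy(float)
    slope_idx = [columns.index(c) for c in random_slopes]
    per_obs = []
    for oid in obs_ids:
        m = (trials["observer_id"] == oid).to_numpy()
        per_obs.append((oid, X[m], y[m], X[m][:, slope_idx]))

    # start from the pooled GLM and a moderate between-observer SD
    pooled = fit_mlcm(
        type(dm)(X, columns, spec, grid), y
    )
    beta0 = pooled.estimates.to_numpy()
    if not np.all(np.isfinite(beta0)):
        beta0 = np.zeros(len(columns))
    p, q = len(columns), len(slope_idx)
    theta0 = np.concatenate([beta0, np.full(q, np.log(0.3))])
    modes = {oid: np.zeros(q) for oid, *_ in per_obs}

    def negloglik(theta):
        beta, sd = theta[:p], np.exp(theta[p:])
        total = 0.0
        for oid, Xs, ys, Zs in per_obs:
            ll, b = _laplace_observer(Xs, ys, Zs, beta, sd, modes[oid])
            modes[oid] = b
            total += ll
        return -total

    res = optimize.minimize(
        negloglik,
        theta0,
        method="L-BFGS-B",
        bounds=[(None, None)] * p + [_LOG_SD_BOUNDS] * q,
        options={"ftol": _OUTER_TOL * 1e-2, "gtol": _OUTER_TOL, "maxiter": 500},
    )
    beta, sd = res.x[:p], np.exp(res.x[p:])
    negloglik(res.x)  # refresh modes at the optimum
    ranef = pd.DataFrame(
        {oid: modes[oid] for oid, *_ in per_obs}, index=list(random_slopes)
    ).T
    return GLMMFit(
        spec=spec,
        grid=grid,
        fixed=pd.Series(beta, index=columns),
        sd_re=pd.Series(sd, index=list(random_slopes)),
        ranef=ranef,
        loglik=-float(res.fun),
        n_params=p + q,
        converged=bool(res.success),
        singular=bool(np.any(sd <= _SINGULAR_SD)),
        group_factor=group_factor,
    )


@dataclass(frozen=True)
class ComparisonRow:
    """One nested likelihood-ratio test."""

    label: str
    chisq: float
    df: int
    p: float
    dAIC: float


@dataclass(frozen=True)
class ComparisonTable:
    """Ordered ladder of nested model comparisons for one task."""

    task: str
    rows: list[ComparisonRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"block": r.label, "Chisq": r.chisq, "df": r.df, "p": r.p, "dAIC": r.dAIC}
                for r in self.rows
            ]
        )


def lrt(nested, full, label: str = "") -> ComparisonRow:
    """Likelihood-ratio test of a nested against a fuller model."""
    df = full.n_params - nested.n_params
    if df <= 0:
        raise ValueError("full model must have more parameters than nested model")
    chisq = 2.0 * (full.loglik - nested.loglik)
    if chisq < -1e-3:
        raise RuntimeError(
            f"full model log-likelihood below nested ({chisq/2:.4f}); optimizer failure"
        )
    chisq = max(chisq, 0.0)
    p = float(chi2.sf(chisq, df))
    return ComparisonRow(label, float(chisq), int(df), p, float(chisq - 2 * df))


_INDEPENDENT_STRUCTURE = {
    "face": "independence_v",
    "voice": "independence_a",
    "stimulus": "independence_v",
}


def model_ladder(
    trials: pd.DataFrame,
    grid: MorphGrid,
    task: str,
    observers: pd.DataFrame | None = None,
) -> ComparisonTable:
    """Run the full nested-comparison ladder on one task's cohort.

    Blocks, in order: judgment-direction group test, observer-sex group
    test, independence vs additive, additive vs gender-magnitude
    interaction, additive vs gender-congruence interaction.
    """
    if task not in _INDEPENDENT_STRUCTURE:
        raise ValueError(f"unknown task {task!r}")
    additive = fit_glmm(trials, grid, ModelSpec("additive", "parametric"))
    rows = []
    for label, factor in (("masculine/feminine", "direction"), ("male/female", "sex")):
        aug = fit_glmm(
            trials,
            grid,
            ModelSpec("additive", "parametric"),
            observers=observers,
            group_factor=factor,
        )
        rows.append(lrt(additive, aug, label))

    indep_structure = _INDEPENDENT_STRUCTURE[task]
    indep = fit_glmm(trials, grid, ModelSpec(indep_structure, "parametric"))
    rows.append(lrt(indep, additive, "independence/additive"))

    for label, structure in (
        ("additive/gender interaction", "additive_plus_magnitude"),
        ("additive/congruence interaction", "additive_plus_congruence"),
    ):
        ext = fit_glmm(trials, grid, ModelSpec(structure, "parametric"))
        rows.append(lrt(additive, ext, label))
    return ComparisonTable(task, rows)


def predictive_accuracy(fit, trials: pd.DataFrame, grid: MorphGrid) -> float:
    """Fraction of trials where the higher-probability choice matches.

    Ties (predicted probability exactly 1/2) score half a point.  For a
    :class:`GLMMFit` the per-observer random-slope predictions are
    included in the linear predictor.
    """
    y = trials["response"].to_numpy(float)
    if isinstance(fit, GLMMFit):
        base_cols = [c for c in fit.fixed.index if ":" not in c]
        dm = encode_trials(trials, grid, fit.spec)
        eta = dm.X @ fit.fixed[base_cols].to_numpy()
        for c in fit.sd_re.index:
            j = base_cols.index(c)
            b = trials["observer_id"].map(fit.ranef[c]).to_numpy(float)
            eta = eta + b * dm.X[:, j]
    else:
        dm = encode_trials(trials, grid, fit.spec)
        eta = dm.X @ fit.estimates.to_numpy()
    pred = np.sign(eta)
    score = np.where(pred == 0, 0.5, (pred > 0) == (y == 1))
    return float(np.mean(score))
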