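"""Two-region bilinear effective-connectivity modeling, desk scale.

The network has two nodes — FFA (fusiform face area) and TVA (temporal
voice area) — whose neural states x follow the bilinear state equation

    dx/dt = (A + sum_j u_j(t) B_j) x + C u(t)

with A the context-independent coupling (negative self-decay on the
diagonal), B_j context-dependent modulations of the couplings, C the
driving-input weights (visual stimulation drives FFA, auditory drives
TVA), and u(t) the experimental input time courses.  Neural states map
to BOLD through convolution with a canonical double-gamma hemodynamic
response, plus white observation noise.

Model evidence is approximated by -BIC/2 from a least-squares fit of the
free A/B/C entries through the forward simulator (the full variational
hemodynamic inversion is out of scope at desk scale; the Bayesian
model-selection layer is agnostic to the evidence source).  Group-level
inference is random-effects Bayesian model selection: a variational
Dirichlet posterior over model frequencies, summarized by exceedance
probabilities at the model or family level.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import digamma

from .design import EventSchedule, build_fmri_schedule

__all__ = [
    "DCMSpec",
    "ModelSpace",
    "BOLDDataset",
    "BMSResult",
    "REGIONS",
    "build_model_space",
    "inputs_from_schedule",
    "simulate_dcm",
    "approximate_evidence",
    "rfx_bms",
    "family_bms",
]

REGIONS = ("FFA", "TVA")

#: Integration step (seconds) and stimulus (boxcar) duration.
DT = 0.1
STIM_DURATION = 0.5

#: Default intrinsic coupling: self-decay plus weak symmetric cross-talk.
DEFAULT_A = np.array([[-0.5, 0.15], [0.15, -0.5]])
#: Default driving strengths (visual -> FFA, auditory -> TVA).
DEFAULT_C = np.array([[0.4, 0.0], [0.0, 0.4]])


@dataclass(frozen=True)
class DCMSpec:
    """One bilinear model: coupling matrices plus input time courses.

    ``u`` has one row per input channel; the first two channels are the
    visual and auditory driving inputs (weighted by C), the remaining
    channels are the modulatory contexts, one B matrix each.
    """

    A: np.ndarray = field(repr=False)
    B: tuple[np.ndarray, ...] = field(repr=False)
    C: np.ndarray = field(repr=False)
    u: np.ndarray = field(repr=False)
    dt: float = DT
    label: str = ""

    def __post_init__(self):
        A = np.asarray(self.A, float)
        if A.shape != (2, 2) or np.any(np.diag(A) >= 0):
            raise ValueError("A must be 2x2 with negative self-decay on the diagonal")


@dataclass(frozen=True)
class ModelSpace:
    """Four modulation hypotheses plus their family partitions.

    Models, in order: (1) no modulation, (2) TVA->FFA only,
    (3) FFA->TVA only, (4) both.  Families: {1,2} vs {3,4} tests the
    FFA->TVA modulation; {1,3} vs {2,4} tests TVA->FFA.
    """

    kind: str
    models: tuple[DCMSpec, ...]
    families: dict[str, tuple[tuple[int, ...], tuple[int, ...]]]


@dataclass(frozen=True)
class BOLDDataset:
    """Simulated per-region BOLD series with its input time courses."""

    y: np.ndarray = field(repr=False)  # (2, n_t)
    u: np.ndarray = field(repr=False)
    dt: float


@dataclass(frozen=True)
class BMSResult:
    """Dirichlet posterior over model (or family) frequencies."""

    labels: tuple[str, ...]
    alpha: np.ndarray
    expected_freq: np.ndarray
    exceedance: np.ndarray


def _hrf(dt: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, unit peak-6s shape."""
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0, duration, dt)
    h = gamma_dist.pdf(t, 6, scale=1.0) - gamma_dist.pdf(t, 16, scale=1.0) / 6.0
    return h / h.sum()


def inputs_from_schedule(
    schedule: EventSchedule,
    kind: str,
    acquisition: int = 0,
    dt: float = DT,
) -> np.ndarray:
    """Build input time courses from one acquisition of an event schedule.

    Channels: visual drive, auditory drive (both on for every
    audio-visual event), then the modulatory contexts — face gender
    present and voice gender present for the ``gender`` space, or the
    single incongruence context for the ``congruence`` space.
    """
    ev = schedule.events[schedule.events["acquisition"] == acquisition]
    onsets = np.concatenate([[0.0], np.cumsum(STIM_DURATION + ev["iti"].to_numpy())])[:-1]
    total = onsets[-1] + STIM_DURATION + float(ev["iti"].iloc[-1]) + 16.0
    n_t = int(np.ceil(total / dt))
    n_mod = 2 if kind == "gender" else 1
    u = np.zeros((2 + n_mod, n_t))
    for onset, (_, row) in zip(onsets, ev.iterrows()):
        i0, i1 = int(onset / dt), int((onset + STIM_DURATION) / dt)
        u[0, i0:i1] = 1.0  # visual drive
        u[1, i0:i1] = 1.0  # auditory drive
        if kind == "gender":
            if row["face"] != "neutral":
                u[2, i0:i1] = 1.0
            if row["voice"] != "neutral":
                u[3, i0:i1] = 1.0
        else:
            incong = {row["face"], row["voice"]} == {"fem", "masc"}
            if incong:
                u[2, i0:i1] = 1.0
    return u


def build_model_space(
    kind: str,
    u: np.ndarray | None = None,
    effect: float = 0.4,
    seed: int | None = None,
) -> ModelSpace:
    """The four-model modulation space for one context family.

    ``gender``: face-gender context modulates FFA->TVA, voice-gender
    context modulates TVA->FFA.  ``congruence``: a single incongruence
    context modulates either or both directions.  ``u`` defaults to the
    inputs of a freshly generated single-acquisition schedule.
    """
    if kind not in ("gender", "congruence"):
        raise ValueError(f"unknown model-space kind {kind!r}")
    if u is None:
        u = inputs_from_schedule(build_fmri_schedule(1, seed=seed), kind)
    n_mod = u.shape[0] - 2

    # entry (row, col) = (target, source): FFA->TVA modulation sits at (1, 0)
    def b_matrices(ffa_to_tva: bool, tva_to_ffa: bool) -> tuple[np.ndarray, ...]:
        mats = [np.zeros((2, 2)) for _ in range(n_mod)]
        if kind == "gender":
            if ffa_to_tva:
                mats[0][1, 0] = effect  # face-gender context
            if tva_to_ffa:
                mats[1][0, 1] = effect  # voice-gender context
        else:
            if ffa_to_tva:
                mats[0][1, 0] = effect
            if tva_to_ffa:
                mats[0][0, 1] = effect
        return tuple(mats)

    combos = [(False, False), (False, True), (True, False), (True, True)]
    labels = ["none", "tva_to_ffa", "ffa_to_tva", "both"]
    models = tuple(
        DCMSpec(DEFAULT_A.copy(), b_matrices(f, t), DEFAULT_C.copy(), u, DT, lab)
        for (f, t), lab in zip(combos, labels)
    )
    families = {
        "ffa_to_tva": ((0, 1), (2, 3)),
        "tva_to_ffa": ((0, 2), (1, 3)),
    }
    return ModelSpace(kind, models, families)


def _integrate(spec: DCMSpec) -> np.ndarray:
    """Fixed-step RK4 integration of the bilinear neural states.

    Inputs are piecewise constant over each step, so the classical RK4
    update for dx/dt = M x + c reduces to x <- R x + S c with step
    matrices R, S precomputed once per distinct input configuration.
    """
    A, C, u, dt = spec.A, spec.C, spec.u, spec.dt
    n_t = u.shape[1]
    uniq, inv = np.unique(u.T, axis=0, return_inverse=True)
    eye = np.eye(2)
    R, Sc = [], []
    for uc in uniq:
        M = A + sum(uc[2 + j] * Bj for j, Bj in enumerate(spec.B))
        M2, M3 = M @ M, M @ M @ M
        M4 = M3 @ M
        R.append(eye + dt * M + dt**2 / 2 * M2 + dt**3 / 6 * M3 + dt**4 / 24 * M4)
        S = dt * (eye + dt / 2 * M + dt**2 / 6 * M2 + dt**3 / 24 * M3)
        Sc.append(S @ (C @ uc[:2]))
    x = np.zeros(2)
    out = np.zeros((2, n_t))
    for i in range(n_t - 1):
        k = inv[i]
        x = R[k] @ x + Sc[k]
        out[:, i + 1] = x
        if i % 200 == 0 and np.abs(x).max() > 1e6:
            raise RuntimeError("divergent neural trajectory; check A stability")
    if np.abs(out).max() > 1e6 or not np.all(np.isfinite(out)):
        raise RuntimeError("divergent neural trajectory; check A stability")
    return out


def _bold(x: np.ndarray, dt: float) -> np.ndarray:
    h = _hrf(dt)
    return np.stack([np.convolve(xi, h)[: x.shape[1]] for xi in x])


def simulate_dcm(
    spec: DCMSpec,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> BOLDDataset:
    """Forward-simulate BOLD: integrate states, convolve HRF, add noise."""
    x = _integrate(spec)
    y = _bold(x, spec.dt)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return BOLDDataset(y, spec.u, spec.dt)


def _free_entries(template: DCMSpec):
    """Free parameters: A off-diagonals, C driving weights, allowed B entries."""
    entries = [("A", 0, 1), ("A", 1, 0), ("C", 0, 0), ("C", 1, 1)]
    for j, Bj in enumerate(template.B):
        for r, c in itertools.product(range(2), range(2)):
            if Bj[r, c] != 0:
                entries.append((f"B{j}", r, c))
    return entries


def _apply_params(template: DCMSpec, entries, values) -> DCMSpec:
    A = template.A.copy()
    C = template.C.copy()
    B = [b.copy() for b in template.B]
    for (name, r, c), v in zip(entries, values):
        if name == "A":
            A[r, c] = v
        elif name == "C":
            C[r, c] = v
        else:
            B[int(name[1:])][r, c] = v
    return replace(template, A=A, B=tuple(B), C=C)


def approximate_evidence(
    data: BOLDDataset,
    template: DCMSpec,
) -> dict:
    """Approximate log model evidence by -BIC/2 from a forward LS fit.

    The free A/B/C entries of ``template`` (its B zeros are structural)
    are fitted by nonlinear least squares through the RK4 forward model,
    and the evidence surrogate -BIC/2 = -(k ln n + n ln(RSS/n))/2 is
    returned along with the fitted parameters and residual variance.
    """
    entries = _free_entries(template)
    if len(entries) > 12:
        raise ValueError("candidate has more than 12 free parameters")
    tmpl = replace(template, u=data.u, dt=data.dt)

    def residuals(values):
        spec = _apply_params(tmpl, entries, values)
        return (simulate_dcm(spec).y - data.y).ravel()

    x0 = np.array(
        [tmpl.A[r, c] if n == "A" else (tmpl.C[r, c] if n == "C" else 0.1)
         for n, r, c in entries]
    )
    res = optimize.least_squares(residuals, x0, xtol=1e-8, ftol=1e-8, max_nfev=400)
    if not res.success and res.status <= 0:
        raise RuntimeError(f"least-squares fit failed: {res.message}")
    n = data.y.size
    k = len(entries)
    rss = float(2 * res.cost)
    sigma2 = max(rss / n, 1e-300)
    log_evidence = -0.5 * (k * np.log(n) + n * np.log(sigma2))
    return {
        "log_evidence": float(log_evidence),
        "params": {f"{nm}[{r},{c}]": float(v) for (nm, r, c), v in zip(entries, res.x)},
        "residual_variance": sigma2,
        "rss": rss,
        "n": n,
        "k": k,
    }


# ---------------------------------------------------------------------------
# Random-effects Bayesian model selection
# ---------------------------------------------------------------------------


def _dirichlet_update(log_evidence: np.ndarray, alpha0: np.ndarray, tol=1e-8):
    """Variational posterior Dirichlet over model frequencies."""
    n_sub, n_mod = log_evidence.shape
    alpha = alpha0.copy()
    for _ in range(500):
        w = log_evidence + digamma(alpha) - digamma(alpha.sum())
        w = w - w.max(axis=1, keepdims=True)
        u = np.exp(w)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    return alpha


def rfx_bms(
    E: np.ndarray | pd.DataFrame,
    alpha0: float | np.ndarray = 1.0,
    n_samples: int = 1_000_000,
    seed: int | None = None,
) -> BMSResult:
    """Random-effects BMS over a subjects x models log-evidence matrix.

    Exceedance probabilities (the probability that each model is the
    most frequent in the population) are estimated by Monte-Carlo
    sampling of the Dirichlet posterior.
    """
    labels = (
        tuple(map(str, E.columns)) if isinstance(E, pd.DataFrame)
        else tuple(f"m{i + 1}" for i in range(np.asarray(E).shape[1]))
    )
    E = np.asarray(E, dtype=float)
    if E.ndim != 2 or E.shape[1] < 2:
        raise ValueError("need a subjects x models matrix with >= 2 models")
    if not np.all(np.isfinite(E)):
        raise ValueError("log evidences must be finite")
    alpha0 = np.broadcast_to(np.asarray(alpha0, float), (E.shape[1],)).copy()
    alpha = _dirichlet_update(E, alpha0)
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    exceed = np.bincount(draws.argmax(axis=1), minlength=E.shape[1]) / n_samples
    return BMSResult(labels, alpha, alpha / alpha.sum(), exceed)


def family_bms(
    E: np.ndarray | pd.DataFrame,
    partition: tuple[tuple[int, ...], ...],
    n_samples: int = 1_000_000,
    seed: int | None = None,
    labels: tuple[str, ...] | None = None,
) -> BMSResult:
    """Family-level random-effects BMS.

    Model priors are set to 1/|family| so every family carries equal
    prior mass; the family exceedance probability is the posterior
    probability that the summed frequency of one family exceeds each
    other family's.
    """
    E_arr = np.asarray(E, dtype=float)
    n_mod = E_arr.shape[1]
    flat = [m for fam in partition for m in fam]
    if sorted(flat) != list(range(n_mod)):
        raise ValueError("partition must cover all models exactly once")
    alpha0 = np.empty(n_mod)
    for fam in partition:
        for m in fam:
            alpha0[m] = 1.0 / len(fam)
    alpha = _dirichlet_update(E_arr, alpha0)
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    fam_freq = np.stack([draws[:, list(fam)].sum(axis=1) for fam in partition], axis=1)
    exceed = np.bincount(fam_freq.argmax(axis=1), minlength=len(partition)) / n_samples
    fam_alpha = np.array([alpha[list(fam)].sum() for fam in partition])
    if labels is None:
        labels = tuple(f"family{i + 1}" for i in range(len(partition)))
    return BMSResult(labels, fam_alpha, fam_alpha / fam_alpha.sum(), exceed)
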