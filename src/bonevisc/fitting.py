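"""Identification of viscoelastic parameters from storage/loss modulus data.

The central operation is a constrained nonlinear least-squares fit of the
generalized Maxwell model to measured storage and loss moduli, minimizing

    D = sum_k [ (E'_fit(w_k) - E'_exp(w_k))^2 + (E''_fit(w_k) - E''_exp(w_k))^2 ]

subject to tau_i > 0 and 0 < g_i < 1.  The constraints are enforced by
reparameterization (log for times and amplitudes), so every local solve is
unconstrained and every returned parameter set satisfies the constraints
strictly.  Multi-start initialization makes the solve robust to the
objective's many local minima; a fixed seed makes it bitwise reproducible.

Two fit modes are provided:

``"prony"``
    Physical-branch parameterization (E_inf, E_1..E_n, tau_1..tau_n) with a
    shared amplitude between storage and loss.  The resulting spectrum
    satisfies the Prony identity E0 = E_inf / (1 - sum g_i) by construction
    and all 2n+1 parameters are identifiable from dense data.

``"reduced"``
    Lumped-amplitude form of the BMD constitutive model for a single sample:
    equilibrium modulus, per-branch storage amplitudes and a loss/storage
    amplitude ratio (2n+2 parameters).  Storage and loss amplitudes are
    decoupled, as in the per-sample constitutive parameter tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .maxwell import (
    BMDConstitutiveParams,
    PowerLawFitResult,
    PronySeries,
    _debye_loss,
    _debye_storage,
    loss_modulus_bmd,
    storage_modulus_bmd,
)
from .synthetic import DMASweep

__all__ = [
    "ModulusDataset",
    "FitConfig",
    "FitResult",
    "GlobalFitResult",
    "objective_D",
    "r_squared",
    "fit_prony",
    "fit_global",
    "fit_powerlaw",
    "extract_steady_state",
    "dataset_from_sweeps",
]


@dataclass(frozen=True)
class ModulusDataset:
    """Per-sample steady-state moduli vs. angular frequency.

    ``points`` are (omega [rad/s], storage [MPa], loss [MPa]) with strictly
    increasing positive omegas and positive moduli.
    """

    sample_id: str
    bmd: float
    omegas: np.ndarray
    storage: np.ndarray
    loss: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.omegas, dtype=float)
        s = np.asarray(self.storage, dtype=float)
        l = np.asarray(self.loss, dtype=float)
        object.__setattr__(self, "omegas", w)
        object.__setattr__(self, "storage", s)
        object.__setattr__(self, "loss", l)
        if self.bmd <= 0:
            raise ValueError("bmd must be > 0")
        if len(w) < 2:
            raise ValueError("dataset needs at least 2 frequency points")
        if w.shape != s.shape or w.shape != l.shape:
            raise ValueError("omegas, storage and loss must have equal length")
        if np.any(w <= 0) or np.any(np.diff(w) <= 0):
            raise ValueError("omegas must be positive and strictly increasing")
        if np.any(s <= 0) or np.any(l <= 0):
            raise ValueError("moduli must be > 0")

    @property
    def n_points(self) -> int:
        return len(self.omegas)


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for :func:`fit_prony` / :func:`fit_global`.

    ``n_starts`` local solves are run from randomized initial points;
    relaxation-time starts are log-spaced over one decade beyond the data's
    frequency window on each side, weights drawn uniform(0.05, 0.95), and
    amplitudes seeded from the data extremes.
    """

    n_starts: int = 32
    max_iter: int = 2000
    tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a per-sample fit.

    The identified model is carried twice: in lumped form (equilibrium
    modulus, per-branch storage amplitudes ``storage_amplitude * g_i``,
    loss amplitude) and, when representable, as a
    :class:`BMDConstitutiveParams` whose power terms evaluate to the same
    lumped amplitudes at the sample's BMD.  That representative is not
    unique — a single-density dataset cannot separate an amplitude into
    coefficient and exponent — and is provided for schema compatibility
    with published parameter tables.
    """

    sample_id: str
    bmd: float
    mode: str
    order: int
    equilibrium_modulus: float
    storage_amplitude: float
    loss_amplitude: float
    weights: tuple[float, ...]
    relaxation_times: tuple[float, ...]
    params: BMDConstitutiveParams
    objective_D: float
    r2_storage: float
    r2_loss: float
    r2_joint: float
    n_starts: int
    converged: bool
    seed: int
    warnings: tuple[str, ...] = ()

    @property
    def spectrum(self) -> PronySeries:
        """The fitted spectrum as a :class:`PronySeries`.

        In ``"prony"`` mode this is a consistent spectrum with
        ``E0 = storage_amplitude``; in ``"reduced"`` mode the storage
        amplitude plays the role of E0 and the equilibrium modulus is
        independent.
        """
        return PronySeries(
            equilibrium_modulus=self.equilibrium_modulus,
            instantaneous_modulus=self.storage_amplitude,
            weights=self.weights,
            relaxation_times=self.relaxation_times,
        )


@dataclass(frozen=True)
class GlobalFitResult:
    """Outcome of the joint fit of shared constitutive parameters across
    all samples of a study."""

    params: BMDConstitutiveParams
    objective_D: float
    r2_storage: float
    r2_loss: float
    r2_joint: float
    n_starts: int
    converged: bool
    seed: int


# ---------------------------------------------------------------------------
# objective and diagnostics


def objective_D(dataset: ModulusDataset, params: BMDConstitutiveParams) -> float:
    """Sum of squared storage and loss residuals (MPa^2) of the constitutive
    model against the dataset, evaluated at the dataset's BMD."""
    e_s = storage_modulus_bmd(params, dataset.bmd, dataset.omegas)
    e_l = loss_modulus_bmd(params, dataset.bmd, dataset.omegas)
    return float(
        np.sum((e_s - dataset.storage) ** 2) + np.sum((e_l - dataset.loss) ** 2)
    )


def _r2_arrays(
    storage_fit: np.ndarray,
    loss_fit: np.ndarray,
    storage_exp: np.ndarray,
    loss_exp: np.ndarray,
) -> tuple[float, float, float]:
    def one(fit: np.ndarray, exp: np.ndarray) -> float:
        ss_tot = float(np.sum((exp - exp.mean()) ** 2))
        ss_res = float(np.sum((fit - exp) ** 2))
        if ss_tot == 0.0:
            raise ValueError("R^2 undefined: zero variance in target channel")
        return 1.0 - ss_res / ss_tot

    r2_s = one(storage_fit, storage_exp)
    r2_l = one(loss_fit, loss_exp)
    # joint R^2 pools residuals about the per-channel means
    ss_tot = float(
        np.sum((storage_exp - storage_exp.mean()) ** 2)
        + np.sum((loss_exp - loss_exp.mean()) ** 2)
    )
    ss_res = float(
        np.sum((storage_fit - storage_exp) ** 2) + np.sum((loss_fit - loss_exp) ** 2)
    )
    return r2_s, r2_l, 1.0 - ss_res / ss_tot


def r_squared(
    dataset: ModulusDataset, params: BMDConstitutiveParams
) -> tuple[float, float, float]:
    """(R^2 storage, R^2 loss, joint R^2) of the model against the dataset.

    Each channel uses ``1 - SS_res / SS_tot`` about that channel's mean; the
    joint value pools both channels' residual and total sums of squares.
    Raises if a target channel has zero variance.
    """
    e_s = storage_modulus_bmd(params, dataset.bmd, dataset.omegas)
    e_l = loss_modulus_bmd(params, dataset.bmd, dataset.omegas)
    return _r2_arrays(np.asarray(e_s), np.asarray(e_l), dataset.storage, dataset.loss)


# ---------------------------------------------------------------------------
# per-sample fit


# clamp for the log/exp reparameterization: keeps trial parameters finite
# (exp(+-250) is astronomically far outside any physical modulus or time
# scale) without ever binding at a realistic optimum
_LOG_CLIP = 250.0


def _expc(z: np.ndarray) -> np.ndarray:
    return np.exp(np.clip(z, -_LOG_CLIP, _LOG_CLIP))


def _model_prony(theta: np.ndarray, w: np.ndarray, order: int):
    e_inf = _expc(theta[0])
    e_i = _expc(theta[1 : 1 + order])
    taus = _expc(theta[1 + order :])
    x = w[:, None] * taus
    return e_inf + _debye_storage(x) @ e_i, _debye_loss(x) @ e_i


def _model_reduced(theta: np.ndarray, w: np.ndarray, order: int):
    e_eq = _expc(theta[0])
    ratio = _expc(theta[1])
    a_i = _expc(theta[2 : 2 + order])
    taus = _expc(theta[2 + order :])
    x = w[:, None] * taus
    return e_eq + _debye_storage(x) @ a_i, ratio * (_debye_loss(x) @ a_i)


def _tau_start_grid(omegas: np.ndarray, order: int) -> np.ndarray:
    # one decade beyond the data window on each side
    lo = 0.1 / omegas.max()
    hi = 10.0 / omegas.min()
    if order == 1:
        return np.array([np.sqrt(lo * hi)])
    return np.geomspace(lo, hi, order)


def _initial_points(
    dataset: ModulusDataset, order: int, mode: str, config: FitConfig,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    w = dataset.omegas
    tau0 = _tau_start_grid(w, order)
    e_min = float(dataset.storage.min())
    dyn = max(float(dataset.storage.max() - dataset.storage.min()),
              2.0 * float(dataset.loss.max()), 1e-6 * e_min)
    starts = []
    for k in range(config.n_starts):
        if k == 0:
            taus = tau0
            u = np.full(order, 0.5)
            jitter_eq = 1.0
        else:
            taus = tau0 * rng.lognormal(0.0, 0.5, size=order)
            u = rng.uniform(0.05, 0.95, size=order)
            jitter_eq = rng.lognormal(0.0, 0.1)
        e_i = dyn * u / u.sum()
        if mode == "prony":
            theta = np.concatenate(
                ([np.log(e_min * jitter_eq)], np.log(e_i), np.log(taus))
            )
        else:
            ratio = 2.0 * float(dataset.loss.max()) / dyn
            theta = np.concatenate(
                ([np.log(e_min * jitter_eq), np.log(ratio)],
                 np.log(e_i), np.log(taus))
            )
        starts.append(theta)
    return starts


def _representative_params(
    e_eq: float, c_storage: float, c_loss: float,
    weights: tuple[float, ...], taus: tuple[float, ...],
    rho: float,
) -> tuple[BMDConstitutiveParams, list[str]]:
    """A constitutive-parameter row whose power terms reproduce the lumped
    amplitudes at density ``rho``: A = E_eq with m = 0, the exponent n chosen
    so A rho^n equals the storage amplitude, and B equal to the loss
    amplitude with q = 0.  Non-unique by construction."""
    notes: list[str] = []
    log_rho = np.log(rho)
    if abs(log_rho) < 1e-12:
        # at rho = 1 a power of rho cannot separate the two storage
        # amplitudes; report exponents 0 and the raw amplitudes
        notes.append(
            "rho = 1: equilibrium and dynamic storage amplitudes cannot both "
            "be encoded through powers of rho; use the lumped fields"
        )
        exp_n = 0.0
        amp_A = e_eq
    else:
        amp_A = e_eq
        exp_n = float(np.log(c_storage / e_eq) / log_rho)
    params = BMDConstitutiveParams(
        amp_A=amp_A, exp_m=0.0, exp_n=exp_n,
        amp_B=c_loss, exp_q=0.0,
        weights=weights, relaxation_times=taus, bmd=rho,
    )
    return params, notes


def fit_prony(
    dataset: ModulusDataset,
    order: int = 4,
    config: FitConfig | None = None,
    seed: int = 0,
    mode: str = "reduced",
) -> FitResult:
    """Fit an ``order``-branch generalized Maxwell model to one dataset.

    Minimizes the sum of squared storage and loss residuals by multi-start
    local least squares; constraints (tau_i > 0, 0 < g_i < 1) hold by
    reparameterization.  Deterministic for fixed ``(dataset, config, seed)``.
    Relaxation times are returned sorted ascending.

    When the number of free parameters exceeds the number of observations
    (2 per frequency point) the result carries an identifiability warning
    instead of raising: sparse-frequency DMA protocols are routinely fit
    this way, and the returned parameters are then one representative of a
    continuum of equally good solutions.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if mode not in ("prony", "reduced"):
        raise ValueError(f"unknown fit mode {mode!r}")
    config = config or FitConfig()
    rng = np.random.default_rng(seed)
    notes: list[str] = []

    n_params = (1 + 2 * order) if mode == "prony" else (2 + 2 * order)
    n_obs = 2 * dataset.n_points
    if n_obs < n_params:
        notes.append(
            f"under-determined fit: {n_params} parameters from {n_obs} "
            "observations; returned parameters are not unique"
        )

    model = _model_prony if mode == "prony" else _model_reduced
    target = np.concatenate([dataset.storage, dataset.loss])

    def residuals(theta: np.ndarray) -> np.ndarray:
        e_s, e_l = model(theta, dataset.omegas, order)
        return np.concatenate([e_s, e_l]) - target

    best = None
    any_success = False
    for theta0 in _initial_points(dataset, order, mode, config, rng):
        res = optimize.least_squares(
            residuals, theta0, method="trf",
            ftol=config.tol, xtol=config.tol, gtol=config.tol,
            max_nfev=config.max_iter,
        )
        any_success = any_success or res.status > 0
        if best is None or res.cost < best.cost:
            best = res

    theta = best.x
    if mode == "prony":
        e_eq = float(_expc(theta[0]))
        e_i = _expc(theta[1 : 1 + order])
        taus = _expc(theta[1 + order :])
        e0 = e_eq + float(e_i.sum())
        g = e_i / e0
        c_storage = c_loss = e0
    else:
        e_eq = float(_expc(theta[0]))
        ratio = float(_expc(theta[1]))
        a_i = _expc(theta[2 : 2 + order])
        taus = _expc(theta[2 + order :])
        # normalization convention: largest weight is 1/2
        c_storage = 2.0 * float(a_i.max())
        g = a_i / c_storage
        c_loss = ratio * c_storage

    idx = np.argsort(taus)
    g_sorted = tuple(float(x) for x in g[idx])
    tau_sorted = tuple(float(x) for x in taus[idx])

    e_s_fit, e_l_fit = model(theta, dataset.omegas, order)
    d_value = float(np.sum((e_s_fit - dataset.storage) ** 2)
                    + np.sum((e_l_fit - dataset.loss) ** 2))
    r2_s, r2_l, r2_j = _r2_arrays(
        np.asarray(e_s_fit), np.asarray(e_l_fit), dataset.storage, dataset.loss
    )

    params, p_notes = _representative_params(
        e_eq, c_storage, c_loss, g_sorted, tau_sorted, dataset.bmd
    )
    notes.extend(p_notes)

    return FitResult(
        sample_id=dataset.sample_id,
        bmd=dataset.bmd,
        mode=mode,
        order=order,
        equilibrium_modulus=e_eq,
        storage_amplitude=c_storage,
        loss_amplitude=c_loss,
        weights=g_sorted,
        relaxation_times=tau_sorted,
        params=params,
        objective_D=d_value,
        r2_storage=r2_s,
        r2_loss=r2_l,
        r2_joint=r2_j,
        n_starts=config.n_starts,
        converged=any_success,
        seed=seed,
        warnings=tuple(notes),
    )


# ---------------------------------------------------------------------------
# global (shared-exponent) fit


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def fit_global(
    datasets: Sequence[ModulusDataset],
    order: int = 4,
    config: FitConfig | None = None,
    seed: int = 0,
) -> GlobalFitResult:
    """Jointly fit one shared constitutive parameter set (A, m, n, B, q,
    g_i, tau_i) to every sample's data, pooling residuals across samples.

    Unlike the per-sample fit, the BMD exponents are identifiable here
    because the amplitudes are observed at several densities.  Weights are
    constrained to (0, 1) by a logistic transform, times and amplitudes by
    log transforms.
    """
    if len(datasets) < 2:
        raise ValueError("global fit needs at least 2 samples")
    config = config or FitConfig()
    rng = np.random.default_rng(seed)

    rhos = np.array([d.bmd for d in datasets])
    all_w = [d.omegas for d in datasets]
    target = np.concatenate(
        [np.concatenate([d.storage, d.loss]) for d in datasets]
    )

    def unpack(theta):
        log_a, m, n, log_b, q = theta[:5]
        g = _sigmoid(np.clip(theta[5 : 5 + order], -_LOG_CLIP, _LOG_CLIP))
        taus = _expc(theta[5 + order :])
        return float(_expc(log_a)), m, n, float(_expc(log_b)), q, g, taus

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, m, n, b, q, g, taus = unpack(theta)
        out = []
        for rho, w in zip(rhos, all_w):
            x = w[:, None] * taus
            e_s = a * rho**m + a * rho**n * (_debye_storage(x) @ g)
            e_l = b * rho**q * (_debye_loss(x) @ g)
            out.append(np.concatenate([e_s, e_l]))
        return np.concatenate(out) - target

    # data-driven anchors for the starts
    e_eq_est = np.array([d.storage.min() for d in datasets])
    slope, intercept = np.polyfit(np.log(rhos), np.log(e_eq_est), 1)
    w_all = np.concatenate(all_w)
    tau0 = _tau_start_grid(w_all, order)
    loss_max = max(float(d.loss.max()) for d in datasets)

    best = None
    any_success = False
    for k in range(config.n_starts):
        if k == 0:
            m0, n0, q0 = slope, slope, 0.0
            a0 = np.exp(intercept)
            b0 = 2.0 * loss_max
            g0 = np.full(order, 0.3)
            taus0 = tau0
        else:
            m0 = slope + rng.normal(0, 1)
            n0 = slope + rng.normal(0, 1)
            q0 = rng.normal(0, 1)
            a0 = np.exp(intercept) * rng.lognormal(0, 0.3)
            b0 = 2.0 * loss_max * rng.lognormal(0, 0.3)
            g0 = rng.uniform(0.05, 0.95, size=order)
            taus0 = tau0 * rng.lognormal(0, 0.5, size=order)
        theta0 = np.concatenate(
            ([np.log(a0), m0, n0, np.log(b0), q0],
             np.log(g0 / (1 - g0)), np.log(taus0))
        )
        res = optimize.least_squares(
            residuals, theta0, method="trf",
            ftol=config.tol, xtol=config.tol, gtol=config.tol,
            max_nfev=config.max_iter,
        )
        any_success = any_success or res.status > 0
        if best is None or res.cost < best.cost:
            best = res

    a, m, n, b, q, g, taus = unpack(best.x)
    g = np.clip(g, 1e-12, 1.0 - 1e-12)  # keep strict (0, 1) after rounding
    idx = np.argsort(taus)
    params = BMDConstitutiveParams(
        amp_A=float(a), exp_m=float(m), exp_n=float(n),
        amp_B=float(b), exp_q=float(q),
        weights=tuple(float(x) for x in g[idx]),
        relaxation_times=tuple(float(x) for x in taus[idx]),
    )

    fit_s, fit_l, exp_s, exp_l = [], [], [], []
    for d in datasets:
        fit_s.append(np.asarray(storage_modulus_bmd(params, d.bmd, d.omegas)))
        fit_l.append(np.asarray(loss_modulus_bmd(params, d.bmd, d.omegas)))
        exp_s.append(d.storage)
        exp_l.append(d.loss)
    r2_s, r2_l, r2_j = _r2_arrays(
        np.concatenate(fit_s), np.concatenate(fit_l),
        np.concatenate(exp_s), np.concatenate(exp_l),
    )
    d_value = sum(objective_D(d, params) for d in datasets)

    return GlobalFitResult(
        params=params,
        objective_D=float(d_value),
        r2_storage=r2_s, r2_loss=r2_l, r2_joint=r2_j,
        n_starts=config.n_starts, converged=any_success, seed=seed,
    )


# ---------------------------------------------------------------------------
# power law and steady-state extraction


def fit_powerlaw(
    bmds: Sequence[float], equilibrium_moduli: Sequence[float]
) -> PowerLawFitResult:
    """Fit ``E_inf = a * rho^b`` to (BMD, equilibrium modulus) pairs.

    Linear least squares on (ln rho, ln E_inf) provides the starting point,
    refined by nonlinear least squares on the original scale; R^2 is
    reported on the original scale.
    """
    rho = np.asarray(bmds, dtype=float)
    e = np.asarray(equilibrium_moduli, dtype=float)
    if len(rho) < 2 or len(rho) != len(e):
        raise ValueError("need >= 2 (bmd, modulus) pairs of equal length")
    if np.any(rho <= 0) or np.any(e <= 0):
        raise ValueError("bmds and moduli must be > 0")

    b0, log_a0 = np.polyfit(np.log(rho), np.log(e), 1)

    def model(r, a, b):
        return a * r**b

    popt, _ = optimize.curve_fit(
        model, rho, e, p0=(np.exp(log_a0), b0), maxfev=10000
    )
    a_hat, b_hat = float(popt[0]), float(popt[1])
    resid = e - model(rho, a_hat, b_hat)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((e - e.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res <= 1e-20 * float(np.sum(e**2)) else -np.inf
    else:
        r2 = 1.0 - ss_res / ss_tot
    return PowerLawFitResult(coefficient=a_hat, exponent=b_hat, r_squared=r2)


def extract_steady_state(
    sweep: DMASweep, tail_fraction: float = 0.25
) -> tuple[float, float]:
    """Steady-state (storage, loss) moduli of a sweep: the mean of each
    series over the final ``tail_fraction`` of the sweep duration.

    The start-up transient decays within the first minutes of the 20-minute
    protocol, so the tail mean estimates the stationary modulus while
    averaging down measurement noise.
    """
    if not 0.0 < tail_fraction <= 1.0:
        raise ValueError("tail_fraction must lie in (0, 1]")
    if len(sweep.times) < 4:
        raise ValueError("sweep needs >= 4 time points")
    t_cut = sweep.times[-1] - tail_fraction * sweep.duration
    mask = sweep.times >= t_cut
    if not mask.any():
        raise ValueError("empty tail window")
    return (
        float(sweep.storage_series[mask].mean()),
        float(sweep.loss_series[mask].mean()),
    )


def dataset_from_sweeps(
    sample_id: str,
    bmd: float,
    sweeps: Sequence[DMASweep],
    tail_fraction: float = 0.25,
    angular_frequency: bool = True,
) -> ModulusDataset:
    """Collapse a sample's frequency sweeps to one steady-state dataset,
    one (omega, E', E'') point per sweep, sorted by frequency."""
    if not sweeps:
        raise ValueError("no sweeps supplied")
    rows = []
    for sw in sorted(sweeps, key=lambda s: s.frequency):
        e_s, e_l = extract_steady_state(sw, tail_fraction)
        w = 2.0 * np.pi * sw.frequency if angular_frequency else sw.frequency
        rows.append((w, e_s, e_l))
    arr = np.array(rows)
    return ModulusDataset(
        sample_id=sample_id, bmd=bmd,
        omegas=arr[:, 0], storage=arr[:, 1], loss=arr[:, 2],
    )
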