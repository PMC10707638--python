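"""Generalized Maxwell (Prony-series) forward models in time and frequency domain.

A generalized Maxwell material is a parallel assembly of ``n`` spring–dashpot
branches plus an equilibrium spring.  Its relaxation modulus is an exponential
sum

    E(t) = E_inf + sum_i E_i * exp(-t / tau_i),        tau_i = eta_i / E_i,

and the corresponding storage and loss moduli under harmonic loading at
angular frequency ``omega`` are Debye sums

    E'(w) = E_inf + sum_i E_i * (tau_i w)^2 / (1 + (tau_i w)^2)
    E''(w) =         sum_i E_i * (tau_i w)   / (1 + (tau_i w)^2).

The Prony parameterization replaces the branch moduli ``E_i`` with
dimensionless weights ``g_i = E_i / E0`` relative to the instantaneous
modulus ``E0``.  For alveolar cancellous bone the moduli additionally scale
with bone mineral density ``rho`` (g/cm^3) through power laws; see
:class:`BMDConstitutiveParams`.

All moduli are in MPa, times in seconds, angular frequencies in rad/s.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

__all__ = [
    "PronySeries",
    "MaxwellBranchSet",
    "BMDConstitutiveParams",
    "PowerLawFitResult",
    "InconsistentSpectrumWarning",
    "relaxation_modulus",
    "storage_modulus",
    "loss_modulus",
    "storage_modulus_bmd",
    "loss_modulus_bmd",
    "to_prony",
    "from_prony",
    "equilibrium_powerlaw",
]

# relative tolerance under which two relaxation times are considered identical
# and their weights merged (canonical form)
_TAU_MERGE_RTOL = 1e-9


class InconsistentSpectrumWarning(UserWarning):
    """The spectrum violates the standard identity E0 = E_inf / (1 - sum g_i)."""


def _canonical_tau_weights(
    weights: Sequence[float],
    taus: Sequence[float],
    merge: bool = True,
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Sort by relaxation time ascending; optionally merge near-duplicate
    times by summing their weights."""
    if len(weights) != len(taus):
        raise ValueError(
            f"weights ({len(weights)}) and relaxation_times ({len(taus)}) "
            "must have equal length"
        )
    order = np.argsort(np.asarray(taus, dtype=float), kind="stable")
    g_out: list[float] = []
    t_out: list[float] = []
    for k in order:
        g, t = float(weights[k]), float(taus[k])
        if merge and t_out and abs(t - t_out[-1]) <= _TAU_MERGE_RTOL * t_out[-1]:
            g_out[-1] += g
        else:
            g_out.append(g)
            t_out.append(t)
    return tuple(g_out), tuple(t_out)


@dataclass(frozen=True)
class PronySeries:
    """Relaxation spectrum of one sample in Prony form.

    Parameters
    ----------
    equilibrium_modulus : float
        Long-time / zero-frequency modulus ``E_inf`` (MPa), >= 0.
    instantaneous_modulus : float
        Zero-time / infinite-frequency modulus ``E0`` (MPa), > 0.
    weights : tuple of float
        Dimensionless branch weights ``g_i = E_i / E0``, each in (0, 1).
    relaxation_times : tuple of float
        Branch time constants ``tau_i`` (s), each > 0.  Stored sorted
        ascending; near-duplicate times are merged by summing weights.

    Notes
    -----
    ``equilibrium_modulus`` and ``instantaneous_modulus`` are stored as
    mutually independent amplitudes.  The standard Prony identity
    ``E0 = E_inf / (1 - sum g_i)`` is *not* enforced, because published
    parameter tables for bone routinely violate it (weight sums above one);
    use :meth:`is_consistent` to check it, or :meth:`consistent` to build a
    spectrum that satisfies it by construction.
    """

    equilibrium_modulus: float
    instantaneous_modulus: float
    weights: tuple[float, ...]
    relaxation_times: tuple[float, ...]

    def __post_init__(self) -> None:
        g, t = _canonical_tau_weights(self.weights, self.relaxation_times)
        object.__setattr__(self, "weights", g)
        object.__setattr__(self, "relaxation_times", t)
        if self.equilibrium_modulus < 0:
            raise ValueError("equilibrium_modulus must be >= 0")
        if self.instantaneous_modulus <= 0:
            raise ValueError("instantaneous_modulus must be > 0")
        if any(tau <= 0 for tau in self.relaxation_times):
            raise ValueError("all relaxation times must be > 0")
        if any(not 0.0 < gi < 1.0 for gi in self.weights):
            raise ValueError("all weights g_i must lie strictly in (0, 1)")

    @property
    def order(self) -> int:
        """Number of Maxwell branches ``n``."""
        return len(self.weights)

    @classmethod
    def consistent(
        cls,
        equilibrium_modulus: float,
        weights: Sequence[float],
        relaxation_times: Sequence[float],
    ) -> "PronySeries":
        """Build a spectrum obeying ``E0 = E_inf / (1 - sum g_i)``.

        Requires ``sum g_i < 1`` and ``equilibrium_modulus > 0``.
        """
        s = float(np.sum(weights))
        if not s < 1.0:
            raise ValueError(f"sum of weights must be < 1, got {s}")
        if equilibrium_modulus <= 0:
            raise ValueError("a consistent spectrum needs equilibrium_modulus > 0")
        return cls(
            equilibrium_modulus=equilibrium_modulus,
            instantaneous_modulus=equilibrium_modulus / (1.0 - s),
            weights=tuple(float(g) for g in weights),
            relaxation_times=tuple(float(t) for t in relaxation_times),
        )

    def is_consistent(self, rtol: float = 1e-9) -> bool:
        """Whether ``E0 == E_inf / (1 - sum g_i)`` holds to relative ``rtol``."""
        s = sum(self.weights)
        if s >= 1.0 or self.equilibrium_modulus == 0.0:
            return False
        e0 = self.equilibrium_modulus / (1.0 - s)
        return math.isclose(e0, self.instantaneous_modulus, rel_tol=rtol)


@dataclass(frozen=True)
class MaxwellBranchSet:
    """Generalized Maxwell model in physical branch parameters.

    Each branch ``i`` is a spring of modulus ``E_i`` (MPa) in series with a
    dashpot of viscosity ``eta_i`` (MPa s); the branch relaxation time is
    ``tau_i = eta_i / E_i``.
    """

    equilibrium_modulus: float
    branch_moduli: tuple[float, ...]
    branch_viscosities: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "branch_moduli", tuple(float(e) for e in self.branch_moduli)
        )
        object.__setattr__(
            self,
            "branch_viscosities",
            tuple(float(h) for h in self.branch_viscosities),
        )
        if len(self.branch_moduli) != len(self.branch_viscosities):
            raise ValueError("branch_moduli and branch_viscosities length mismatch")
        if self.equilibrium_modulus < 0:
            raise ValueError("equilibrium_modulus must be >= 0")
        if any(e <= 0 for e in self.branch_moduli):
            raise ValueError("all branch moduli E_i must be > 0")
        if any(h <= 0 for h in self.branch_viscosities):
            raise ValueError("all branch viscosities eta_i must be > 0")

    @property
    def relaxation_times(self) -> tuple[float, ...]:
        """Branch time constants ``tau_i = eta_i / E_i`` (s)."""
        return tuple(
            h / e for h, e in zip(self.branch_viscosities, self.branch_moduli)
        )

    @classmethod
    def from_times(
        cls,
        equilibrium_modulus: float,
        branch_moduli: Sequence[float],
        relaxation_times: Sequence[float],
    ) -> "MaxwellBranchSet":
        """Construct from (E_inf, E_i, tau_i), deriving eta_i = E_i * tau_i."""
        return cls(
            equilibrium_modulus=equilibrium_modulus,
            branch_moduli=tuple(float(e) for e in branch_moduli),
            branch_viscosities=tuple(
                float(e) * float(t) for e, t in zip(branch_moduli, relaxation_times)
            ),
        )


@dataclass(frozen=True)
class BMDConstitutiveParams:
    """Parameters of the BMD-dependent constitutive model.

    The storage and loss moduli of a sample with bone mineral density
    ``rho`` (g/cm^3) are

        E'(rho, w)  = A rho^m + A rho^n * sum_i g_i (tau_i w)^2 / (1 + (tau_i w)^2)
        E''(rho, w) = B rho^q * sum_i g_i (tau_i w)   / (1 + (tau_i w)^2)

    so ``A rho^m`` is the equilibrium modulus, ``A rho^n`` the dynamic
    storage amplitude and ``B rho^q`` the loss amplitude.  The exponent
    written ``n`` in the model is stored as ``exp_n`` to avoid a collision
    with the model order.  The canonical model order is 4.
    """

    amp_A: float
    exp_m: float
    exp_n: float
    amp_B: float
    exp_q: float
    weights: tuple[float, ...]
    relaxation_times: tuple[float, ...]
    bmd: float | None = field(default=None)

    def __post_init__(self) -> None:
        # sorted ascending but never merged: published parameter rows may
        # legitimately repeat a relaxation time across branches
        g, t = _canonical_tau_weights(
            self.weights, self.relaxation_times, merge=False
        )
        object.__setattr__(self, "weights", g)
        object.__setattr__(self, "relaxation_times", t)
        if any(tau <= 0 for tau in self.relaxation_times):
            raise ValueError("all relaxation times must be > 0")
        if any(not 0.0 < gi < 1.0 for gi in self.weights):
            raise ValueError("all weights g_i must lie strictly in (0, 1)")
        if self.amp_A <= 0 or self.amp_B <= 0:
            raise ValueError("amplitudes A and B must be > 0")

    @property
    def order(self) -> int:
        return len(self.weights)

    def equilibrium_modulus(self, rho: float) -> float:
        """Zero-frequency storage modulus ``A rho^m`` (MPa)."""
        _check_rho(rho)
        return self.amp_A * rho**self.exp_m

    def to_dict(self) -> dict:
        """Serialize with short field names matching the parameter-table
        convention (A, m, n, B, q, g1..gn, tau1..taun, BMD)."""
        d: dict = {
            "A": self.amp_A,
            "m": self.exp_m,
            "n": self.exp_n,
            "B": self.amp_B,
            "q": self.exp_q,
        }
        for i, g in enumerate(self.weights, 1):
            d[f"g{i}"] = g
        for i, t in enumerate(self.relaxation_times, 1):
            d[f"tau{i}"] = t
        if self.bmd is not None:
            d["BMD"] = self.bmd
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BMDConstitutiveParams":
        n = 1
        while f"g{n + 1}" in d:
            n += 1
        return cls(
            amp_A=float(d["A"]),
            exp_m=float(d["m"]),
            exp_n=float(d["n"]),
            amp_B=float(d["B"]),
            exp_q=float(d["q"]),
            weights=tuple(float(d[f"g{i}"]) for i in range(1, n + 1)),
            relaxation_times=tuple(float(d[f"tau{i}"]) for i in range(1, n + 1)),
            bmd=float(d["BMD"]) if "BMD" in d else None,
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "BMDConstitutiveParams":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class PowerLawFitResult:
    """A fitted power law ``E = coefficient * rho^exponent``."""

    coefficient: float
    exponent: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError("coefficient must be > 0")
        if self.r_squared > 1.0:
            raise ValueError("r_squared cannot exceed 1")


Spectrum = Union[PronySeries, MaxwellBranchSet]


def _check_nonneg(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be >= 0")
    return arr


def _check_rho(rho: float) -> float:
    if rho <= 0:
        raise ValueError("bone mineral density rho must be > 0")
    return float(rho)


def _branch_amplitudes(spectrum: Spectrum) -> tuple[float, np.ndarray, np.ndarray]:
    """(E_inf, E_i array, tau_i array) for either parameterization."""
    if isinstance(spectrum, PronySeries):
        e_i = spectrum.instantaneous_modulus * np.asarray(spectrum.weights)
        taus = np.asarray(spectrum.relaxation_times)
        return spectrum.equilibrium_modulus, e_i, taus
    if isinstance(spectrum, MaxwellBranchSet):
        return (
            spectrum.equilibrium_modulus,
            np.asarray(spectrum.branch_moduli),
            np.asarray(spectrum.relaxation_times),
        )
    raise TypeError(f"unsupported spectrum type {type(spectrum).__name__}")


def relaxation_modulus(spectrum: Spectrum, t) -> np.ndarray | float:
    """Relaxation modulus ``E(t) = E_inf + sum_i E_i exp(-t/tau_i)`` (MPa).

    ``t`` may be a scalar or array of times (s), all >= 0.  Monotone
    non-increasing in ``t``; ``E(0) = E_inf + sum E_i`` and
    ``E(t) -> E_inf`` as ``t -> inf``.
    """
    t_arr = _check_nonneg(t, "time t")
    e_inf, e_i, taus = _branch_amplitudes(spectrum)
    out = e_inf + np.exp(-t_arr[..., None] / taus) @ e_i
    return out if np.ndim(t) else float(out)


def _debye_storage(x: np.ndarray) -> np.ndarray:
    return x * x / (1.0 + x * x)


def _debye_loss(x: np.ndarray) -> np.ndarray:
    return x / (1.0 + x * x)


def storage_modulus(spectrum: Spectrum, omega) -> np.ndarray | float:
    """Storage modulus ``E'(w)`` (MPa) at angular frequency ``w`` (rad/s).

    ``E'(w) = E_inf + sum_i E_i (tau_i w)^2 / (1 + (tau_i w)^2)``;
    non-decreasing in ``w`` with ``E'(0) = E_inf``.
    """
    w = _check_nonneg(omega, "angular frequency omega")
    e_inf, e_i, taus = _branch_amplitudes(spectrum)
    out = e_inf + _debye_storage(w[..., None] * taus) @ e_i
    return out if np.ndim(omega) else float(out)


def loss_modulus(spectrum: Spectrum, omega) -> np.ndarray | float:
    """Loss modulus ``E''(w)`` (MPa) at angular frequency ``w`` (rad/s).

    ``E''(w) = sum_i E_i (tau_i w) / (1 + (tau_i w)^2)``; zero at ``w = 0``,
    vanishing as ``w -> inf``, each term peaking at ``w = 1/tau_i`` with
    value ``E_i / 2``.
    """
    w = _check_nonneg(omega, "angular frequency omega")
    _, e_i, taus = _branch_amplitudes(spectrum)
    out = _debye_loss(w[..., None] * taus) @ e_i
    return out if np.ndim(omega) else float(out)


def storage_modulus_bmd(
    params: BMDConstitutiveParams, rho: float, omega
) -> np.ndarray | float:
    """BMD-dependent storage modulus (MPa): ``A rho^m + A rho^n * Debye sum``."""
    rho = _check_rho(rho)
    w = _check_nonneg(omega, "angular frequency omega")
    g = np.asarray(params.weights)
    taus = np.asarray(params.relaxation_times)
    dyn = _debye_storage(w[..., None] * taus) @ g
    out = params.amp_A * rho**params.exp_m + params.amp_A * rho**params.exp_n * dyn
    return out if np.ndim(omega) else float(out)


def loss_modulus_bmd(
    params: BMDConstitutiveParams, rho: float, omega
) -> np.ndarray | float:
    """BMD-dependent loss modulus (MPa): ``B rho^q * Debye sum``; 0 at w=0."""
    rho = _check_rho(rho)
    w = _check_nonneg(omega, "angular frequency omega")
    g = np.asarray(params.weights)
    taus = np.asarray(params.relaxation_times)
    out = params.amp_B * rho**params.exp_q * (_debye_loss(w[..., None] * taus) @ g)
    return out if np.ndim(omega) else float(out)


def to_prony(branches: MaxwellBranchSet) -> PronySeries:
    """Convert branch parameters to Prony form.

    Uses ``E0 = E_inf + sum E_i`` and ``g_i = E_i / E0``; the result always
    satisfies the standard identity ``E0 = E_inf / (1 - sum g_i)``.
    """
    e0 = branches.equilibrium_modulus + sum(branches.branch_moduli)
    return PronySeries(
        equilibrium_modulus=branches.equilibrium_modulus,
        instantaneous_modulus=e0,
        weights=tuple(e / e0 for e in branches.branch_moduli),
        relaxation_times=branches.relaxation_times,
    )


def from_prony(spectrum: PronySeries) -> MaxwellBranchSet:
    """Convert Prony form back to physical branches ``E_i = g_i E0``,
    ``eta_i = E_i tau_i``.

    Raises for ``sum g_i >= 1`` (the implied equilibrium spring would have
    non-positive modulus).  Warns if the spectrum's stored equilibrium
    modulus is inconsistent with ``E0 (1 - sum g_i)``, in which case the
    round trip through :func:`to_prony` will not reproduce ``E0``.
    """
    s = sum(spectrum.weights)
    if s >= 1.0:
        raise ValueError(
            f"invalid spectrum: sum of weights {s:.6g} >= 1 implies a "
            "non-positive equilibrium modulus"
        )
    if not spectrum.is_consistent(rtol=1e-9):
        warnings.warn(
            "spectrum violates E0 = E_inf / (1 - sum g_i); branch set uses the "
            "stored E_inf and E_i = g_i E0 as-is",
            InconsistentSpectrumWarning,
            stacklevel=2,
        )
    e_i = [g * spectrum.instantaneous_modulus for g in spectrum.weights]
    return MaxwellBranchSet(
        equilibrium_modulus=spectrum.equilibrium_modulus,
        branch_moduli=tuple(e_i),
        branch_viscosities=tuple(
            e * t for e, t in zip(e_i, spectrum.relaxation_times)
        ),
    )


def equilibrium_powerlaw(rho, fit: PowerLawFitResult) -> np.ndarray | float:
    """Evaluate ``coefficient * rho^exponent`` (MPa) at density ``rho``."""
    r = np.asarray(rho, dtype=float)
    if np.any(r <= 0):
        raise ValueError("bone mineral density rho must be > 0")
    out = fit.coefficient * r**fit.exponent
    return out if np.ndim(rho) else float(out)
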