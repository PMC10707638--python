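"""Synthetic DMA study generator for alveolar cancellous bone.

Emulates a nine-sample mandibular study: cube samples from three tooth
regions (canine, premolar, molar sites) at three root depths (cervical,
middle, apical), each characterized by a micro-CT bone mineral density
(BMD) and tested in compressive DMA at four frequencies (0.5, 1, 2, 5 Hz)
for 20 minutes each at 25 degC.

Steady-state moduli come from the BMD-dependent generalized-Maxwell model
(:mod:`bonevisc.maxwell`); on top of that the generator adds a saturating
exponential start-up transient (stiffer samples show a deeper, more visible
rise) and multiplicative Gaussian noise.  Everything is reproducible from a
single integer seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .maxwell import (
    BMDConstitutiveParams,
    loss_modulus_bmd,
    storage_modulus_bmd,
)

__all__ = [
    "ToothRegion",
    "RootDepth",
    "SampleRecord",
    "DMASweep",
    "StudyConfig",
    "REFERENCE_BMD",
    "REFERENCE_TRABECULAR_NUMBER",
    "reference_constitutive_params",
    "powerlaw_constitutive_params",
    "trabecular_number",
    "simulate_sweep",
    "make_study",
    "EQUILIBRIUM_POWERLAW_COEFF",
    "EQUILIBRIUM_POWERLAW_EXP",
]


class ToothRegion(str, enum.Enum):
    """Mandibular tooth region a sample was cut from."""

    REGION1_CANINE = "region1_canine"
    REGION2_PREMOLAR = "region2_premolar"
    REGION3_MOLAR = "region3_molar"


class RootDepth(str, enum.Enum):
    """Depth along the tooth root."""

    CERVICAL = "cervical"
    MIDDLE = "middle"
    APICAL = "apical"


# Measured BMD (g/cm^3) of the nine reference cube samples, keyed by
# (tooth region, root depth).  Anterior sites and cervical depths are denser.
REFERENCE_BMD: dict[tuple[ToothRegion, RootDepth], float] = {
    (ToothRegion.REGION1_CANINE, RootDepth.CERVICAL): 0.926,
    (ToothRegion.REGION1_CANINE, RootDepth.MIDDLE): 0.766,
    (ToothRegion.REGION1_CANINE, RootDepth.APICAL): 0.735,
    (ToothRegion.REGION2_PREMOLAR, RootDepth.CERVICAL): 0.862,
    (ToothRegion.REGION2_PREMOLAR, RootDepth.MIDDLE): 0.652,
    (ToothRegion.REGION2_PREMOLAR, RootDepth.APICAL): 0.616,
    (ToothRegion.REGION3_MOLAR, RootDepth.CERVICAL): 0.826,
    (ToothRegion.REGION3_MOLAR, RootDepth.MIDDLE): 0.638,
    (ToothRegion.REGION3_MOLAR, RootDepth.APICAL): 0.604,
}

# Trabecular count density (1/pixel) measured in the micro-CT region of
# interest, keyed by BMD.  Monotone increasing in BMD.
REFERENCE_TRABECULAR_NUMBER: dict[float, float] = {
    0.604: 0.061,
    0.616: 0.065,
    0.638: 0.068,
    0.652: 0.072,
    0.735: 0.078,
    0.766: 0.082,
    0.826: 0.089,
    0.862: 0.094,
    0.926: 0.142,
}

# Reported power law tying equilibrium modulus (MPa) to BMD (g/cm^3):
# E_inf = 1213.482 * rho^2.039.
EQUILIBRIUM_POWERLAW_COEFF = 1213.482
EQUILIBRIUM_POWERLAW_EXP = 2.039

# Fitted fourth-order constitutive parameter rows for the nine reference
# samples, keyed by BMD: (A, m, n, B, q, (g1..g4), (tau1..tau4)).
_REFERENCE_PARAMS: dict[float, tuple] = {
    0.926: (48.810, -38.381, -6.959, 14.580, -7.91,
            (0.999, 0.972, 0.581, 0.996), (0.022, 0.431, 0.103, 3.844)),
    0.766: (17.970, -14.076, -4.305, 15.373, 6.701,
            (0.405, 0.383, 0.828, 0.735), (0.126, 0.045, 0.533, 0.012)),
    0.735: (3.291, -17.421, -8.118, 3.368, -10.786,
            (0.497, 0.741, 0.892, 0.437), (0.038, 0.008, 0.552, 0.131)),
    0.862: (31.947, -22.076, -10.058, 27.237, -3.148,
            (0.999, 0.839, 0.500, 0.023), (0.522, 0.023, 0.111, 0.003)),
    0.652: (12.497, -9.331, -0.762, 12.082, -4.441,
            (0.625, 0.688, 0.999, 0.554), (0.112, 0.519, 0.024, 0.519)),
    0.616: (9.568, -7.677, -3.609, 11.994, -4.790,
            (0.584, 0.890, 0.578, 0.997), (0.042, 0.010, 0.145, 0.584)),
    0.826: (22.326, -18.518, -3.935, 45.121, -0.156,
            (0.998, 0.629, 0.815, 0.999), (0.021, 0.077, 0.259, 1.057)),
    0.638: (2.834, -11.381, -5.005, 12.816, -4.790,
            (0.824, 0.959, 0.527, 0.520), (0.011, 0.581, 0.142, 0.044)),
    0.604: (9.604, -6.369, -3.774, 12.081, -4.758,
            (0.479, 0.808, 0.503, 0.970), (0.041, 0.011, 0.128, 0.549)),
}


def reference_constitutive_params(bmd: float) -> BMDConstitutiveParams:
    """Return the published constitutive parameter row for one of the nine
    reference BMD values, verbatim.

    Used as simulator ground truth and in round-trip tests.  Raises
    ``KeyError`` for a BMD not in the reference study.
    """
    try:
        a, m, n, b, q, g, tau = _REFERENCE_PARAMS[bmd]
    except KeyError:
        raise KeyError(
            f"BMD {bmd!r} is not one of the nine reference sample densities "
            f"{sorted(_REFERENCE_PARAMS)}"
        ) from None
    return BMDConstitutiveParams(
        amp_A=a, exp_m=m, exp_n=n, amp_B=b, exp_q=q,
        weights=g, relaxation_times=tau, bmd=bmd,
    )


def powerlaw_constitutive_params(
    loss_amp_B: float = 60.0,
    loss_exp_q: float = -2.0,
    weights: Sequence[float] = (0.1, 0.1, 0.1, 0.1),
    relaxation_times: Sequence[float] = (0.01, 0.04, 0.16, 0.64),
) -> BMDConstitutiveParams:
    """A smooth single-parameter-set alternative to the per-sample reference
    rows: equilibrium modulus and dynamic storage amplitude both follow the
    reported BMD power law, and the loss amplitude decays with BMD.

    By construction the steady-state storage modulus is increasing and the
    loss modulus decreasing in BMD at any fixed frequency, matching the
    qualitative experimental finding.  The default relaxation times are
    log-spaced inside the 0.5-5 Hz excitation band (1/omega from 0.032 to
    0.32 s at the 2*pi*f convention) so that every relaxation process of
    the synthetic material — including its equilibrium stiffness — is
    observable by, and identifiable from, the four-frequency protocol.
    """
    return BMDConstitutiveParams(
        amp_A=EQUILIBRIUM_POWERLAW_COEFF,
        exp_m=EQUILIBRIUM_POWERLAW_EXP,
        exp_n=EQUILIBRIUM_POWERLAW_EXP,
        amp_B=loss_amp_B,
        exp_q=loss_exp_q,
        weights=tuple(weights),
        relaxation_times=tuple(relaxation_times),
    )


def trabecular_number(bmd: float) -> float:
    """Trabecular count density (1/pixel) for a given BMD.

    Exact lookup for the nine reference densities; monotone linear
    interpolation (clamped at the ends) otherwise.
    """
    if bmd in REFERENCE_TRABECULAR_NUMBER:
        return REFERENCE_TRABECULAR_NUMBER[bmd]
    xs = np.array(sorted(REFERENCE_TRABECULAR_NUMBER))
    ys = np.array([REFERENCE_TRABECULAR_NUMBER[x] for x in xs])
    return float(np.interp(bmd, xs, ys))


@dataclass(frozen=True)
class SampleRecord:
    """One cube sample of cancellous alveolar bone."""

    sample_id: str
    tooth_region: ToothRegion
    root_depth: RootDepth
    bmd: float
    trabecular_number: float

    def __post_init__(self) -> None:
        if self.bmd <= 0:
            raise ValueError("bmd must be > 0")


@dataclass(frozen=True)
class DMASweep:
    """One time-resolved DMA record at a single drive frequency.

    ``times`` is a uniform grid in seconds; ``storage_series`` and
    ``loss_series`` are the instantaneous storage/loss moduli in MPa.
    Protocol constants (temperature, preload, force amplitude) are carried
    as metadata.
    """

    sample_id: str
    frequency: float
    times: np.ndarray
    storage_series: np.ndarray
    loss_series: np.ndarray
    temperature_c: float = 25.0
    preload_mn: float = 0.5
    force_amplitude_n: float = 5.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.storage_series, dtype=float)
        l = np.asarray(self.loss_series, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "storage_series", s)
        object.__setattr__(self, "loss_series", l)
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("times must be a 1-D grid with >= 2 points")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing and start >= 0")
        if s.shape != t.shape or l.shape != t.shape:
            raise ValueError("series lengths must match times length")
        if np.any(s <= 0) or np.any(l < 0):
            raise ValueError("moduli series must be positive")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


# default BMD layout for the 3 regions x 3 depths design, region-major
_DESIGN_CELLS: tuple[tuple[ToothRegion, RootDepth], ...] = tuple(
    (r, d) for r in ToothRegion for d in RootDepth
)
_DEFAULT_BMDS: tuple[float, ...] = tuple(REFERENCE_BMD[c] for c in _DESIGN_CELLS)


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one synthetic study.

    ``transient_depth`` is the fractional start-up depression ``c`` of the
    storage modulus; ``None`` selects the BMD-dependent default
    ``0.05 + 0.15 * (rho - rho_min) / (rho_max - rho_min)`` so denser
    samples show the more pronounced initial rise seen experimentally.
    ``noise_cv`` is the coefficient of variation of multiplicative Gaussian
    noise.  ``angular_frequency`` selects the ``omega = 2 pi f`` convention
    (``False`` uses ``omega = f`` for sensitivity checks).
    """

    bmds: tuple[float, ...] = _DEFAULT_BMDS
    frequencies: tuple[float, ...] = (0.5, 1.0, 2.0, 5.0)
    sweep_duration: float = 1200.0
    sampling_interval: float = 1.0
    noise_cv: float = 0.02
    transient_depth: float | None = None
    transient_time: float = 120.0
    seed: int = 0
    angular_frequency: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "bmds", tuple(float(b) for b in self.bmds))
        object.__setattr__(
            self, "frequencies", tuple(float(f) for f in self.frequencies)
        )
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.transient_depth is not None and not (
            0.0 <= self.transient_depth < 1.0
        ):
            raise ValueError("transient_depth must lie in [0, 1)")
        if self.sweep_duration <= 0 or self.sampling_interval <= 0:
            raise ValueError("sweep_duration and sampling_interval must be > 0")
        if any(f <= 0 for f in self.frequencies):
            raise ValueError("frequencies must be > 0")

    def depth_for(self, bmd: float) -> float:
        """Transient depth ``c`` for a sample of the given BMD."""
        if self.transient_depth is not None:
            return self.transient_depth
        lo, hi = min(self.bmds), max(self.bmds)
        if hi == lo:
            return 0.05
        return 0.05 + 0.15 * (bmd - lo) / (hi - lo)

    def omega(self, frequency: float) -> float:
        return 2.0 * np.pi * frequency if self.angular_frequency else frequency


def simulate_sweep(
    sample: SampleRecord,
    params: BMDConstitutiveParams,
    frequency: float,
    config: StudyConfig,
    seed: int,
) -> DMASweep:
    """Simulate one frequency sweep of one sample.

    The series are

        E'(t)  = E'_ss  * (1 - c e^{-t/tau_r}) * (1 + eps_t)
        E''(t) = E''_ss * (1 + c e^{-t/tau_r}) * (1 + eps'_t)

    with steady states from the BMD constitutive model at
    ``omega = 2 pi f``, transient depth ``c`` and recovery time ``tau_r``
    from the config, and iid Gaussian ``eps`` with standard deviation
    ``noise_cv``.  The tail mean converges to the steady state as the noise
    vanishes.
    """
    if frequency <= 0:
        raise ValueError("frequency must be > 0")
    w = config.omega(frequency)
    e_storage = storage_modulus_bmd(params, sample.bmd, w)
    e_loss = loss_modulus_bmd(params, sample.bmd, w)
    times = np.arange(0.0, config.sweep_duration + 0.5 * config.sampling_interval,
                      config.sampling_interval)
    c = config.depth_for(sample.bmd)
    envelope = np.exp(-times / config.transient_time)
    rng = np.random.default_rng(seed)
    eps_s = rng.normal(0.0, config.noise_cv, size=times.shape)
    eps_l = rng.normal(0.0, config.noise_cv, size=times.shape)
    storage = e_storage * (1.0 - c * envelope) * (1.0 + eps_s)
    loss = e_loss * (1.0 + c * envelope) * (1.0 + eps_l)
    return DMASweep(
        sample_id=sample.sample_id,
        frequency=frequency,
        times=times,
        storage_series=storage,
        loss_series=loss,
    )


def _sample_records(config: StudyConfig) -> list[SampleRecord]:
    if len(config.bmds) != len(_DESIGN_CELLS):
        raise ValueError(
            f"config.bmds must supply {len(_DESIGN_CELLS)} values for the "
            f"3 regions x 3 depths design, got {len(config.bmds)}"
        )
    records = []
    for (region, depth), bmd in zip(_DESIGN_CELLS, config.bmds):
        region_no = {"region1_canine": 1, "region2_premolar": 2,
                     "region3_molar": 3}[region.value]
        records.append(
            SampleRecord(
                sample_id=f"R{region_no}-{depth.value}",
                tooth_region=region,
                root_depth=depth,
                bmd=bmd,
                trabecular_number=trabecular_number(bmd),
            )
        )
    return records


def make_study(
    config: StudyConfig | None = None,
    params_for: "callable | None" = None,
) -> tuple[list[SampleRecord], list[DMASweep]]:
    """Generate the full synthetic study: 9 samples x 4 frequency sweeps.

    ``params_for(bmd) -> BMDConstitutiveParams`` selects the ground-truth
    model per sample; the default uses the published reference row when the
    BMD is one of the nine reference densities and the smooth power-law
    parameter set otherwise.  Fully reproducible from ``config.seed``.
    """
    config = config or StudyConfig()
    if params_for is None:
        def params_for(bmd: float) -> BMDConstitutiveParams:
            try:
                return reference_constitutive_params(bmd)
            except KeyError:
                return powerlaw_constitutive_params()

    samples = _sample_records(config)
    n_sweeps = len(samples) * len(config.frequencies)
    child_seeds = np.random.SeedSequence(config.seed).generate_state(n_sweeps)
    sweeps = []
    k = 0
    for sample in samples:
        params = params_for(sample.bmd)
        for freq in config.frequencies:
            sweeps.append(
                simulate_sweep(sample, params, freq, config,
                               seed=int(child_seeds[k] % 2**31))
            )
            k += 1
    return samples, sweeps


def noise_free(config: StudyConfig) -> StudyConfig:
    """Copy of ``config`` with noise and transient switched off."""
    return replace(config, noise_cv=0.0, transient_depth=0.0)
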