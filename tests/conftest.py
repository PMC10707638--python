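import numpy as np
import pytest

import bonevisc as bv


@pytest.fixture
def four_branch_spectrum() -> bv.PronySeries:
    """A consistent 4-branch spectrum with well-separated relaxation times,
    used as ground truth in recovery tests."""
    return bv.PronySeries.consistent(
        equilibrium_modulus=500.0,
        weights=(0.15, 0.2, 0.1, 0.12),
        relaxation_times=(0.01, 0.1, 1.0, 10.0),
    )


def dense_dataset_from_params(
    params: bv.BMDConstitutiveParams,
    rho: float,
    f_lo: float = 0.05,
    f_hi: float = 50.0,
    n: int = 30,
    sample_id: str = "synth",
) -> bv.ModulusDataset:
    """Noise-free storage/loss data from the constitutive model on a
    log-spaced frequency grid (Hz), at the angular-frequency convention."""
    w = 2.0 * np.pi * np.geomspace(f_lo, f_hi, n)
    return bv.ModulusDataset(
        sample_id=sample_id,
        bmd=rho,
        omegas=w,
        storage=np.asarray(bv.storage_modulus_bmd(params, rho, w)),
        loss=np.asarray(bv.loss_modulus_bmd(params, rho, w)),
    )


def dense_dataset_from_spectrum(
    spectrum: bv.PronySeries,
    omegas: np.ndarray,
    rho: float = 0.7,
    sample_id: str = "synth",
) -> bv.ModulusDataset:
    return bv.ModulusDataset(
        sample_id=sample_id,
        bmd=rho,
        omegas=omegas,
        storage=np.asarray(bv.storage_modulus(spectrum, omegas)),
        loss=np.asarray(bv.loss_modulus(spectrum, omegas)),
    )
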