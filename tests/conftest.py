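import numpy as np
import pytest

from dtialps import phantom as ph


@pytest.fixture()
def small_spec() -> ph.PhantomSpec:
    """Desk-size isotropic-voxel phantom for fast tests (24x24x12 grid)."""
    return ph.PhantomSpec(grid_shape=(24, 24, 12), voxel_size_mm=(1.0, 1.0, 1.0))


@pytest.fixture()
def default_spec() -> ph.PhantomSpec:
    return ph.PhantomSpec()


def acq_from_tensors(tensors: np.ndarray, scheme: ph.GradientScheme,
                     s0: float = 1.0) -> ph.AcquisitionRealization:
    """Noiseless monoexponential signals straight from a tensor array.

    Independent of simulate_dwi: the attenuation is evaluated per volume with
    an explicit quadratic form, giving the fitting tests an input whose
    ground truth is known exactly.
    """
    t = np.asarray(tensors, dtype=float)
    shape = t.shape[:-2]
    flat = t.reshape(-1, 3, 3)
    sig = np.empty((flat.shape[0], scheme.n_volumes))
    for v in range(scheme.n_volumes):
        g = scheme.directions[v]
        b = scheme.bvalues[v]
        q = np.einsum("nij,i,j->n", flat, g, g)
        sig[:, v] = s0 * np.exp(-b * q)
    return ph.AcquisitionRealization(
        signals=sig.reshape(shape + (scheme.n_volumes,)),
        scheme=scheme, snr_b0=float("inf"),
    )


def random_spd_tensors(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random symmetric-positive-definite tensors at tissue scale (mm^2/s)."""
    a = rng.normal(size=(n, 3, 3))
    spd = np.einsum("nij,nkj->nik", a, a) + 3.0 * np.eye(3)
    return spd * 2e-4
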