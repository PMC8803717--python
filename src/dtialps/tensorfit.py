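"""Diffusion tensor fitting and directional diffusivity maps.

Two routes produce the Dxx/Dyy/Dzz maps the ALPS index needs:

* a standard log-linear (OLS) tensor fit for schemes with >= 6 distinct
  weighted directions, giving the full tensor plus FA/MD; and
* the 3-orthogonal-axis ADC path used by DWI-ALPS, where the per-axis
  apparent diffusion coefficient is read directly from the axis-aligned
  signals (ADC_i = -ln(S_i/S0)/b) without a tensor model.

Both return the diagonal diffusivities in the scanner frame (no eigen
rotation), which is exactly what the ALPS ratio consumes. The fit is plain
OLS on log-signals; voxels with any nonpositive signal are masked out rather
than clamped, and negative fitted diagonals are retained in the tensor result
but excluded from ROI statistics through the fit mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import AcquisitionRealization

__all__ = [
    "SchemeError",
    "TensorFitResult",
    "DiffusivityMaps",
    "design_matrix",
    "fit_tensor_loglinear",
    "maps_from_tensor",
    "maps_from_three_axis",
]


class SchemeError(ValueError):
    """Scheme unsuitable for the requested fitting route."""


def _spacing(affine: np.ndarray | None) -> tuple[float, float, float] | None:
    if affine is None:
        return None
    return tuple(np.linalg.norm(affine[:3, :3], axis=0))


@dataclass
class TensorFitResult:
    """Voxelwise log-linear tensor fit.

    ``tensor_elements`` stacks (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) along the last
    axis; ``fit_mask`` is False wherever any signal was nonpositive.
    """

    tensor_elements: np.ndarray  # (..., 6)
    s0: np.ndarray
    fit_mask: np.ndarray
    residual_rms: np.ndarray
    affine: np.ndarray | None = None


@dataclass
class DiffusivityMaps:
    """Directional diffusivity volumes in the scanner frame.

    ``source`` records whether the maps came from a tensor fit or the 3-axis
    ADC path; the two live on different scales and are never pooled unlabeled.
    ``fit_mask`` additionally excludes voxels with nonpositive diagonals.
    """

    dxx: np.ndarray
    dyy: np.ndarray
    dzz: np.ndarray
    fit_mask: np.ndarray
    source: str  # "tensor" | "three_axis_adc"
    fa: np.ndarray | None = None
    md: np.ndarray | None = None
    affine: np.ndarray | None = None
    voxel_size_mm: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.source == "three_axis_adc" and self.fa is not None:
            raise ValueError("three-axis ADC maps carry no FA")


def design_matrix(directions: np.ndarray, bvalues: np.ndarray) -> np.ndarray:
    """Rows [1, -b gx^2, -b gy^2, -b gz^2, -2b gxgy, -2b gxgz, -2b gygz]
    solving ln S = ln S0 - b g^T D g for (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)."""
    g = np.asarray(directions, dtype=float)
    b = np.asarray(bvalues, dtype=float)[:, None]
    gx, gy, gz = g[:, 0:1], g[:, 1:2], g[:, 2:3]
    return np.hstack(
        [
            np.ones_like(b),
            -b * gx * gx,
            -b * gy * gy,
            -b * gz * gz,
            -2 * b * gx * gy,
            -2 * b * gx * gz,
            -2 * b * gy * gz,
        ]
    )


def fit_tensor_loglinear(acq: AcquisitionRealization) -> TensorFitResult:
    """Ordinary-least-squares tensor fit on log signals, per voxel.

    Requires >= 6 distinct weighted directions plus a b=0 volume (7 usable
    volumes); 3-axis data must go through :func:`maps_from_three_axis`.
    """
    scheme = acq.scheme
    weighted = scheme.bvalues > 0
    distinct = np.unique(np.round(scheme.directions[weighted], 12), axis=0)
    if len(distinct) < 6 or (~weighted).sum() < 1:
        raise SchemeError(
            "tensor fit needs >= 6 distinct weighted directions plus a b=0 volume; "
            "use the 3-axis ADC route for orthogonal-axis data"
        )
    signals = acq.averaged_signals()
    shape = signals.shape[:-1]
    S = signals.reshape(-1, signals.shape[-1])
    mask = np.all(S > 0, axis=1)

    X = design_matrix(scheme.directions, scheme.bvalues)
    rank = np.linalg.matrix_rank(X)
    if rank < 7:
        raise SchemeError("rank-deficient design matrix")

    beta = np.zeros((S.shape[0], 7))
    resid = np.zeros(S.shape[0])
    if mask.any():
        Y = np.log(S[mask])
        sol, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
        beta[mask] = sol.T
        r = Y - beta[mask] @ X.T
        resid[mask] = np.sqrt(np.mean(r * r, axis=1))

    return TensorFitResult(
        tensor_elements=beta[:, 1:].reshape(shape + (6,)),
        s0=np.exp(beta[:, 0]).reshape(shape) * mask.reshape(shape),
        fit_mask=mask.reshape(shape),
        residual_rms=resid.reshape(shape),
        affine=acq.affine,
    )


def _fa_md(elements: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """FA and MD from eigenvalues of the full tensor (in-mask only)."""
    shape = elements.shape[:-1]
    e = elements.reshape(-1, 6)
    m = mask.reshape(-1)
    fa = np.zeros(e.shape[0])
    md = np.zeros(e.shape[0])
    if m.any():
        D = np.zeros((m.sum(), 3, 3))
        xx, yy, zz, xy, xz, yz = e[m].T
        D[:, 0, 0], D[:, 1, 1], D[:, 2, 2] = xx, yy, zz
        D[:, 0, 1] = D[:, 1, 0] = xy
        D[:, 0, 2] = D[:, 2, 0] = xz
        D[:, 1, 2] = D[:, 2, 1] = yz
        lam = np.linalg.eigvalsh(D)
        mean_l = lam.mean(axis=1)
        num = np.sqrt(((lam - mean_l[:, None]) ** 2).sum(axis=1))
        den = np.sqrt((lam**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            fa_m = np.sqrt(1.5) * np.where(den > 0, num / den, 0.0)
        fa[m] = np.clip(fa_m, 0.0, 1.0)
        md[m] = mean_l
    return fa.reshape(shape), md.reshape(shape)


def maps_from_tensor(fit: TensorFitResult) -> DiffusivityMaps:
    """Diagonal diffusivities (scanner frame) plus FA/MD from a tensor fit.

    The ROI-usable mask additionally requires all three diagonals positive.
    """
    el = fit.tensor_elements
    dxx, dyy, dzz = el[..., 0], el[..., 1], el[..., 2]
    mask = fit.fit_mask & (dxx > 0) & (dyy > 0) & (dzz > 0)
    fa, md = _fa_md(el, mask)
    return DiffusivityMaps(
        dxx=dxx, dyy=dyy, dzz=dzz, fit_mask=mask, source="tensor",
        fa=fa, md=md, affine=fit.affine, voxel_size_mm=_spacing(fit.affine),
    )


def maps_from_three_axis(acq: AcquisitionRealization) -> DiffusivityMaps:
    """Per-axis ADC maps from a 3-orthogonal-axis acquisition (DWI-ALPS path).

    ADC_i = -ln(S_i / S0) / b with S0 the mean of the b=0 volumes; voxels
    with nonpositive S_i or S0 are masked. Supersedes an RGB-composite
    visualization step: the per-axis maps are used directly.
    """
    scheme = acq.scheme
    weighted = scheme.bvalues > 0
    dirs = scheme.directions[weighted]
    if scheme.n_axes != 3 or not np.allclose(np.abs(dirs), np.eye(3)[np.abs(dirs).argmax(axis=1)]):
        raise SchemeError("three-axis route requires exactly the coordinate axes")
    signals = acq.averaged_signals()
    s0 = signals[..., ~weighted].mean(axis=-1)
    b = scheme.bvalues[weighted]
    axis_of = np.abs(dirs).argmax(axis=1)
    adc = np.zeros(signals.shape[:-1] + (3,))
    mask = s0 > 0
    for col, (ax, bv) in enumerate(zip(axis_of, b)):
        si = signals[..., np.flatnonzero(weighted)[col]]
        ok = mask & (si > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            adc_i = -np.log(np.where(ok, si / np.where(mask, s0, 1.0), 1.0)) / bv
        adc[..., ax] = np.where(ok, adc_i, 0.0)
        mask = ok
    return DiffusivityMaps(
        dxx=adc[..., 0], dyy=adc[..., 1], dzz=adc[..., 2],
        fit_mask=mask, source="three_axis_adc", affine=acq.affine,
        voxel_size_mm=_spacing(acq.affine),
    )
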