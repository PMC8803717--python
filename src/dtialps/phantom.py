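"""Synthetic corona-radiata diffusion phantom.

The ALPS method exploits a specific geometry at the level of the lateral
ventricle body: projection fibers (corticospinal tract) run inferior-superior
(z), association fibers (superior longitudinal fasciculus) run
anterior-posterior (y), and the perivascular spaces of the medullary veins run
right-left (x), perpendicular to both fiber systems. This module builds voxel
grids of ground-truth diffusion tensors with exactly that arrangement, applies
head/imaging-plane rotations, and simulates Rician-noisy diffusion-weighted
acquisitions under configurable schemes.

Axis convention (0-based voxel indices): axis 0 = x (right-left, low index =
right), axis 1 = y (anterior-posterior), axis 2 = z (inferior-superior).

Perivascular water can be represented two ways:

* ``"tensor"`` (default): the perivascular contribution is folded into the
  voxel tensor as an additive x-aligned diffusivity elevation, so the signal
  is monoexponential and the noiseless pipeline has a closed-form ALPS index.
* ``"pool"``: perivascular water is a separate fast x-aligned diffusion pool
  and the voxel signal is a two-compartment sum of exponentials. This is the
  mode used by the study harness: a non-monoexponential signal is what makes
  the fitted index depend on the gradient direction count, as observed for
  real tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .directions import direction_set

__all__ = [
    "LABEL_CODES",
    "FREE_WATER_DIFFUSIVITY",
    "TE_TO_DIFFUSION_TIME_MS",
    "TIME_REFERENCE_MS",
    "GeometryError",
    "ParameterError",
    "TimeScale",
    "PhantomSpec",
    "GradientScheme",
    "TensorField",
    "AcquisitionRealization",
    "build_corona_radiata_phantom",
    "make_scheme",
    "apply_head_rotation",
    "simulate_dwi",
    "ground_truth_alps",
]

#: Region codes of the label map.
LABEL_CODES = {"background": 0, "csf": 1, "projection": 2, "association": 3}

#: Upper bound for any tissue diffusivity (mm^2/s): free water at body temperature.
FREE_WATER_DIFFUSIVITY = 3.2e-3

#: Echo time (ms) -> diffusion time (ms) pairing of the emulated sequences.
TE_TO_DIFFUSION_TIME_MS = {65.0: 29.0, 85.0: 35.7, 100.0: 40.7}

#: Diffusion time (ms) at which compartment diffusivities are specified.
TIME_REFERENCE_MS = 35.7

#: SNR multiplier per scanner noise profile (same signal model, different
#: noise scale between the two emulated 3 T systems).
SCANNER_SNR_FACTOR = {"centurian": 1.0, "prisma": 0.9}


class GeometryError(ValueError):
    """Phantom geometry is inconsistent (e.g. ROI center outside its region)."""


class ParameterError(ValueError):
    """Unsupported acquisition or phantom parameter."""


@dataclass(frozen=True)
class TimeScale:
    """Monotone diffusion-time dependence, as a dimensionless multiplier.

    ``scale(t) = (s_inf + (1 - s_inf) exp(-t/tau)) / (same at t_ref)`` —
    a decaying exponential toward the long-time plateau ``s_inf``, normalized
    to 1 at the reference diffusion time so that compartment tables keep their
    nominal values at the standard sequence. This is a simulator convention
    (restricted water loses apparent diffusivity as diffusion time grows),
    not a biophysical model.
    """

    s_inf: float
    tau_ms: float
    t_ref_ms: float = TIME_REFERENCE_MS

    def __call__(self, t_ms: float) -> float:
        raw = self.s_inf + (1.0 - self.s_inf) * np.exp(-t_ms / self.tau_ms)
        ref = self.s_inf + (1.0 - self.s_inf) * np.exp(-self.t_ref_ms / self.tau_ms)
        return float(raw / ref)


def default_compartment_diffusivities() -> dict[str, tuple[float, float, float]]:
    """Principal diffusivities (mm^2/s) along (x, y, z) per region.

    Projection fibers are z-principal, association fibers y-principal; the
    perpendicular values are typical deep-white-matter radial diffusivities.
    CSF and the extra-phantom background are isotropic.
    """
    return {
        "background": (0.0, 0.0, 0.0),  # air: no signal
        "csf": (3.0e-3, 3.0e-3, 3.0e-3),
        "projection": (0.40e-3, 0.45e-3, 1.40e-3),
        "association": (0.40e-3, 1.30e-3, 0.45e-3),
    }


def default_time_dependence() -> dict[str, TimeScale]:
    """Time-dependence classes: weakly restricted tissue, strongly
    time-dependent perivascular water (so the index falls as diffusion time
    grows, matching the observed TE direction)."""
    return {
        "tissue": TimeScale(s_inf=0.90, tau_ms=40.0),
        "pvs": TimeScale(s_inf=0.45, tau_ms=40.0),
    }


def default_roi_centers(grid_shape: tuple[int, int, int]) -> dict[tuple[str, str], tuple[float, float, float]]:
    """Mirror-symmetric ROI centers at the middle of each region slab.

    Centers sit on half-voxel coordinates so that even-sided masks are
    symmetric about them.
    """
    nx, ny, nz = grid_shape
    q = nx // 4
    cy, cz = (ny - 1) / 2.0, (nz - 1) / 2.0
    assoc_r = (q - 1) / 2.0
    proj_r = q + (q - 1) / 2.0
    mid = (nx - 1) / 2.0
    return {
        ("right", "association"): (assoc_r, cy, cz),
        ("right", "projection"): (proj_r, cy, cz),
        ("left", "projection"): (2 * mid - proj_r, cy, cz),
        ("left", "association"): (2 * mid - assoc_r, cy, cz),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth description of one phantom subject.

    Parameters
    ----------
    grid_shape : voxel counts along (x, y, z).
    voxel_size_mm : spacing per axis. Default in-plane spacing is the
        200 mm FOV / 256 interpolated matrix = 0.78125 mm with 3 mm slices.
    compartment_diffusivities : region -> (dx, dy, dz) principal
        diffusivities in mm^2/s at the reference diffusion time.
    pvs_fraction : weight in [0, 1] of the x-aligned perivascular water
        component added to projection and association regions.
    pvs_diffusivities : principal diffusivities of the perivascular pool
        along (x, y, z); fast along x, restricted across it.
    time_dependence : compartment-class -> TimeScale multiplier.
    roi_centers : (hemisphere, region) -> voxel coordinate of ROI centers;
        must be mirror-symmetric about the midsagittal plane.
    assoc_shortening : fraction of the left association slab removed from
        its anterior end; models the short-superior-longitudinal-fasciculus
        anatomy that can push an automated ROI off the tract. Off by default.
    seed : RNG seed recorded alongside the phantom description.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 24)
    voxel_size_mm: tuple[float, float, float] = (0.78125, 0.78125, 3.0)
    compartment_diffusivities: Mapping[str, tuple[float, float, float]] = field(
        default_factory=default_compartment_diffusivities
    )
    pvs_fraction: float = 0.12
    pvs_diffusivities: tuple[float, float, float] = (3.0e-3, 0.30e-3, 0.30e-3)
    time_dependence: Mapping[str, TimeScale] = field(default_factory=default_time_dependence)
    roi_centers: Mapping[tuple[str, str], tuple[float, float, float]] | None = None
    assoc_shortening: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for region, d in self.compartment_diffusivities.items():
            d = np.asarray(d, dtype=float)
            if region != "background" and (np.any(d <= 0) or np.any(d >= FREE_WATER_DIFFUSIVITY)):
                raise ParameterError(
                    f"{region} diffusivities {tuple(d)} outside (0, {FREE_WATER_DIFFUSIVITY})"
                )
        dp = self.compartment_diffusivities["projection"]
        da = self.compartment_diffusivities["association"]
        if not (dp[2] >= dp[0] and dp[2] >= dp[1]):
            raise GeometryError("projection principal axis must be z")
        if not (da[1] >= da[0] and da[1] >= da[2]):
            raise GeometryError("association principal axis must be y")
        if not 0.0 <= self.pvs_fraction <= 1.0:
            raise ParameterError("pvs_fraction must lie in [0, 1]")
        if self.roi_centers is not None:
            mid = (self.grid_shape[0] - 1) / 2.0
            for (hemi, region), c in self.roi_centers.items():
                mirror = ("left" if hemi == "right" else "right", region)
                cm = self.roi_centers[mirror]
                if not (
                    np.isclose(c[0] - mid, mid - cm[0])
                    and np.isclose(c[1], cm[1])
                    and np.isclose(c[2], cm[2])
                ):
                    raise GeometryError(f"roi centers {c} / {cm} not mirror-symmetric")

    def resolved_roi_centers(self) -> dict[tuple[str, str], tuple[float, float, float]]:
        if self.roi_centers is not None:
            return dict(self.roi_centers)
        return default_roi_centers(self.grid_shape)


@dataclass(frozen=True)
class GradientScheme:
    """One diffusion acquisition scheme: directions, b-values, timing.

    ``directions`` are unit vectors in the imaging-plane frame; rows aligned
    with ``bvalues`` (entries with b = 0 mark non-diffusion-weighted volumes
    and their direction row is ignored).
    """

    directions: np.ndarray
    bvalues: np.ndarray
    n_axes: int
    averages: int = 1
    diffusion_time_ms: float | None = None
    te_ms: float | None = None
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "directions", np.asarray(self.directions, dtype=float))
        object.__setattr__(self, "bvalues", np.asarray(self.bvalues, dtype=float))
        if self.directions.shape != (len(self.bvalues), 3):
            raise ParameterError("directions must be (n_volumes, 3) aligned with bvalues")
        if not np.any(self.bvalues == 0):
            raise ParameterError("scheme requires at least one b=0 volume")
        dwi = self.bvalues > 0
        norms = np.linalg.norm(self.directions[dwi], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-8):
            raise ParameterError("diffusion-weighted directions must be unit vectors")
        if self.averages < 1:
            raise ParameterError("averages must be >= 1")

    @property
    def n_volumes(self) -> int:
        return len(self.bvalues)


@dataclass
class TensorField:
    """Voxel grid of ground-truth diffusion tensors plus region labels.

    ``tissue`` holds the tissue tensor per voxel; ``pvs`` the perivascular
    contribution (an additive tensor elevation in ``"tensor"`` mode, the
    perivascular pool's own tensor in ``"pool"`` mode, weighted by
    ``pvs_weight``). ``tensors`` exposes the composite (zero-b-limit
    effective) tensor at the reference diffusion time.
    """

    tissue: np.ndarray  # (nx, ny, nz, 3, 3), mm^2/s
    pvs: np.ndarray  # (nx, ny, nz, 3, 3)
    pvs_weight: np.ndarray  # (nx, ny, nz), pool weight (0 in tensor mode)
    labels: np.ndarray  # (nx, ny, nz) int codes per LABEL_CODES
    affine: np.ndarray  # voxel -> mm
    voxel_size_mm: tuple[float, float, float]
    mode: str = "tensor"  # "tensor" | "pool"
    time_dependence: Mapping[str, TimeScale] = field(default_factory=default_time_dependence)
    roi_centers: dict = field(default_factory=dict)

    @property
    def tensors(self) -> np.ndarray:
        if self.mode == "tensor":
            return self.tissue + self.pvs
        w = self.pvs_weight[..., None, None]
        return (1.0 - w) * self.tissue + w * self.pvs

    def time_scales(self, diffusion_time_ms: float) -> tuple[float, float]:
        """(tissue, pvs) time multipliers at the given diffusion time.

        The tissue scale multiplies the tissue tensor. The perivascular
        scale multiplies the *contribution* of perivascular water — the
        additive x elevation in tensor mode, the pool weight in pool mode —
        modeling reduced apparent perivascular water at longer diffusion
        times (restricted exchange), so the index falls as diffusion time
        grows.
        """
        st = self.time_dependence["tissue"](diffusion_time_ms)
        sp = self.time_dependence["pvs"](diffusion_time_ms)
        return st, sp


@dataclass
class AcquisitionRealization:
    """One simulated (or loaded) diffusion-weighted acquisition.

    ``signals`` is (x, y, z, volume). When ``averaged`` is True the averaging
    has been applied and the volume count equals ``scheme.n_volumes``;
    otherwise each of the ``averages`` repeats is stored.
    """

    signals: np.ndarray
    scheme: GradientScheme
    snr_b0: float
    rotation_deg: float = 0.0
    scanner_profile: str = "centurian"
    averaged: bool = True
    affine: np.ndarray | None = None

    def averaged_signals(self) -> np.ndarray:
        if self.averaged:
            return self.signals
        nvol = self.scheme.n_volumes
        shape = self.signals.shape[:-1] + (self.scheme.averages, nvol)
        return self.signals.reshape(shape).mean(axis=-2)


def _region_labels(spec: PhantomSpec) -> np.ndarray:
    """Slab geometry: association | projection | projection | association
    quarters along x, a thin anterior CSF slab, air margins in z."""
    nx, ny, nz = spec.grid_shape
    labels = np.zeros(spec.grid_shape, dtype=np.int8)
    q = nx // 4
    x = np.arange(nx)[:, None, None]
    y = np.arange(ny)[None, :, None]
    z = np.arange(nz)[None, None, :]
    y0, z0, z1 = ny // 8, nz // 12, nz - nz // 12
    in_tissue = (y >= y0) & (z >= z0) & (z < z1)
    assoc = ((x < q) | (x >= 3 * q)) & in_tissue
    if spec.assoc_shortening > 0:
        # shorten the LEFT association slab from the anterior end
        cut = ny - int(round(spec.assoc_shortening * (ny - y0)))
        assoc &= ~((x >= 3 * q) & (y >= cut))
    proj = (x >= q) & (x < 3 * q) & in_tissue
    labels[np.broadcast_to(proj, labels.shape)] = LABEL_CODES["projection"]
    labels[np.broadcast_to(assoc, labels.shape)] = LABEL_CODES["association"]
    csf = (y < y0) & (z >= z0) & (z < z1)
    labels[np.broadcast_to(csf, labels.shape)] = LABEL_CODES["csf"]
    return labels


def build_corona_radiata_phantom(spec: PhantomSpec, pvs_as_pool: bool = False) -> TensorField:
    """Build the ground-truth tensor field for one phantom subject.

    Projection voxels are z-principal, association voxels y-principal, and
    both receive an x-aligned perivascular contribution weighted by
    ``spec.pvs_fraction`` — either folded into the voxel tensor (default) or
    kept as a separate fast pool (``pvs_as_pool=True``).
    """
    labels = _region_labels(spec)
    shape = spec.grid_shape
    tissue = np.zeros(shape + (3, 3))
    pvs = np.zeros(shape + (3, 3))
    pvs_weight = np.zeros(shape)

    for region, code in LABEL_CODES.items():
        mask = labels == code
        if not mask.any():
            continue
        d = np.asarray(spec.compartment_diffusivities[region], dtype=float)
        tissue[mask] = np.diag(d)

    pvs_tensor = np.diag(np.asarray(spec.pvs_diffusivities, dtype=float))
    for region in ("projection", "association"):
        mask = labels == LABEL_CODES[region]
        dx = spec.compartment_diffusivities[region][0]
        if pvs_as_pool:
            pvs[mask] = pvs_tensor
            pvs_weight[mask] = spec.pvs_fraction
        else:
            elevation = spec.pvs_fraction * (spec.pvs_diffusivities[0] - dx)
            e = np.zeros((3, 3))
            e[0, 0] = elevation
            pvs[mask] = e

    affine = np.diag(list(spec.voxel_size_mm) + [1.0])
    field_ = TensorField(
        tissue=tissue,
        pvs=pvs,
        pvs_weight=pvs_weight,
        labels=labels,
        affine=affine,
        voxel_size_mm=spec.voxel_size_mm,
        mode="pool" if pvs_as_pool else "tensor",
        time_dependence=dict(spec.time_dependence),
        roi_centers=spec.resolved_roi_centers(),
    )

    expected = {"projection": LABEL_CODES["projection"], "association": LABEL_CODES["association"]}
    for (hemi, region), c in field_.roi_centers.items():
        idx = tuple(int(round(v)) for v in c)
        if not all(0 <= i < n for i, n in zip(idx, shape)):
            raise GeometryError(f"ROI center {c} ({hemi} {region}) outside grid {shape}")
        if labels[idx] != expected[region]:
            raise GeometryError(
                f"ROI center {c} ({hemi} {region}) lies in region code {labels[idx]}, "
                f"not {region}"
            )
    return field_


def make_scheme(n_axes: int, averages: int, te_ms: float, b: float = 1000.0, label: str = "") -> GradientScheme:
    """Build a scheme with one b=0 volume plus ``n_axes`` weighted directions.

    The diffusion time is looked up from the echo time via the fixed
    (TE, diffusion-time) pairing of the emulated sequences:
    65→29, 85→35.7, 100→40.7 ms.
    """
    if n_axes not in (3, 12, 30):
        raise ParameterError(f"unsupported MPG axis count {n_axes}")
    te = float(te_ms)
    if te not in TE_TO_DIFFUSION_TIME_MS:
        raise ParameterError(
            f"TE {te_ms} ms has no paired diffusion time (known: {sorted(TE_TO_DIFFUSION_TIME_MS)})"
        )
    dirs = direction_set(n_axes)
    directions = np.vstack([np.zeros(3), dirs])
    bvalues = np.concatenate([[0.0], np.full(n_axes, float(b))])
    return GradientScheme(
        directions=directions,
        bvalues=bvalues,
        n_axes=n_axes,
        averages=averages,
        diffusion_time_ms=TE_TO_DIFFUSION_TIME_MS[te],
        te_ms=te,
        label=label,
    )


def _rotation_about_x(pitch_deg: float) -> np.ndarray:
    a = np.deg2rad(pitch_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def apply_head_rotation(field_: TensorField, pitch_deg: float) -> TensorField:
    """Pitch the anatomy about the x (right-left) axis.

    Models both chin-up head positioning and an imaging-plane tilt (the
    gradients stay aligned to the imaging plane, so either is a rotation of
    the anatomy relative to the gradient frame). Tensors are conjugated
    D' = R D R^T and the label/tensor geometry is resampled under the same
    rotation (nearest-neighbor) about the grid center in mm coordinates.
    """
    if abs(pitch_deg) > 45:
        raise ParameterError("|pitch| must be <= 45 degrees")
    if pitch_deg == 0.0:
        return field_
    R = _rotation_about_x(pitch_deg)
    shape = field_.labels.shape
    vs = np.asarray(field_.voxel_size_mm)
    center = (np.asarray(shape) - 1) / 2.0 * vs

    idx = np.indices(shape).reshape(3, -1).T * vs  # mm coords of voxel centers
    src = (idx - center) @ R + center  # R^-1 applied: R is orthogonal, x @ R = R.T @ x
    src_vox = np.rint(src / vs).astype(int)
    inside = np.all((src_vox >= 0) & (src_vox < np.asarray(shape)), axis=1)
    src_vox = np.clip(src_vox, 0, np.asarray(shape) - 1)
    flat = np.ravel_multi_index(src_vox.T, shape)

    def resample(vol: np.ndarray, fill: float = 0.0) -> np.ndarray:
        out = vol.reshape((-1,) + vol.shape[3:])[flat]
        out[~inside] = fill
        return out.reshape(vol.shape)

    labels = resample(field_.labels.astype(field_.labels.dtype))
    tissue = np.einsum("ij,...jk,lk->...il", R, resample(field_.tissue), R)
    pvs = np.einsum("ij,...jk,lk->...il", R, resample(field_.pvs), R)
    pvs_weight = resample(field_.pvs_weight)
    return replace(
        field_,
        tissue=tissue,
        pvs=pvs,
        pvs_weight=pvs_weight,
        labels=labels,
    )


def simulate_dwi(
    field_: TensorField,
    scheme: GradientScheme,
    snr_b0: float = 40.0,
    seed: int = 0,
    scanner_profile: str = "centurian",
    store_averaged: bool = True,
) -> AcquisitionRealization:
    """Simulate magnitude DWI signals for a tensor field.

    Noiseless signal per voxel and volume: S = S0 exp(-b g^T D(t) g) (tensor
    mode) or the two-pool sum in pool mode, with D(t) the diffusion-time
    scaled tensors. Rician noise at ``snr_b0`` (referenced to the tissue b=0
    signal) is drawn independently per average; magnitudes are averaged
    before storage unless ``store_averaged`` is False. ``scanner_profile``
    scales the SNR (the two emulated scanners share the signal model and
    differ only in noise scale).
    """
    if not snr_b0 > 0:
        raise ParameterError("snr_b0 must be positive")
    if scanner_profile not in SCANNER_SNR_FACTOR:
        raise ParameterError(f"unknown scanner profile {scanner_profile!r}")
    t = scheme.diffusion_time_ms if scheme.diffusion_time_ms is not None else TIME_REFERENCE_MS
    st, sp = field_.time_scales(t)
    if not (np.isfinite(st) and np.isfinite(sp)):
        raise ParameterError("non-finite diffusivity after diffusion-time model")

    shape = field_.labels.shape
    nvox = int(np.prod(shape))
    s0 = (field_.labels.reshape(-1) != LABEL_CODES["background"]).astype(float)

    G = scheme.directions
    b = scheme.bvalues
    Qt = np.einsum("nij,vi,vj->nv", field_.tissue.reshape(nvox, 3, 3), G, G)
    Qp = np.einsum("nij,vi,vj->nv", field_.pvs.reshape(nvox, 3, 3), G, G)
    if field_.mode == "pool":
        w = np.clip(field_.pvs_weight.reshape(nvox, 1) * sp, 0.0, 1.0)
        signal = s0[:, None] * ((1.0 - w) * np.exp(-b * st * Qt) + w * np.exp(-b * Qp))
    else:
        signal = s0[:, None] * np.exp(-b * (st * Qt + sp * Qp))

    effective_snr = snr_b0 * SCANNER_SNR_FACTOR[scanner_profile]
    if np.isinf(effective_snr):
        if store_averaged:
            out = signal
        else:
            out = np.tile(signal[:, None, :], (1, scheme.averages, 1)).reshape(nvox, -1)
    else:
        sigma = 1.0 / effective_snr  # S0 of tissue is 1
        rng = np.random.default_rng(seed)
        reps = rng.normal(size=(nvox, scheme.averages, scheme.n_volumes, 2)) * sigma
        mags = np.sqrt((signal[:, None, :] + reps[..., 0]) ** 2 + reps[..., 1] ** 2)
        out = mags.mean(axis=1) if store_averaged else mags.reshape(nvox, -1)

    return AcquisitionRealization(
        signals=out.reshape(shape + (-1,)),
        scheme=scheme,
        snr_b0=snr_b0,
        rotation_deg=0.0,
        scanner_profile=scanner_profile,
        averaged=store_averaged,
        affine=field_.affine,
    )


def ground_truth_alps(spec: PhantomSpec, diffusion_time_ms: float = TIME_REFERENCE_MS) -> float:
    """Closed-form ALPS index of the (tensor-mode) phantom compartment table.

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc), with the
    perivascular elevation on the x components and the diffusion-time scales
    applied to each compartment class.
    """
    st = spec.time_dependence["tissue"](diffusion_time_ms)
    sp = spec.time_dependence["pvs"](diffusion_time_ms)
    dp = np.asarray(spec.compartment_diffusivities["projection"], dtype=float)
    da = np.asarray(spec.compartment_diffusivities["association"], dtype=float)
    ex_p = spec.pvs_fraction * (spec.pvs_diffusivities[0] - dp[0])
    ex_a = spec.pvs_fraction * (spec.pvs_diffusivities[0] - da[0])
    dxx_proj = dp[0] * st + ex_p * sp
    dxx_assoc = da[0] * st + ex_a * sp
    dyy_proj = dp[1] * st
    dzz_assoc = da[2] * st
    return float(((dxx_proj + dxx_assoc) / 2.0) / ((dyy_proj + dzz_assoc) / 2.0))
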