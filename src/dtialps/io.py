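"""Readers/writers and provenance utilities.

Diffusion data travel as NIfTI-1 volumes with FSL-dialect gradient tables:
``.bval`` is one whitespace-separated row of b-values, ``.bvec`` three rows
(x, y, z components), one column per volume. Result tables are CSV; reports
are JSON with a provenance block (package version, seed, config hash).
Outputs are never silently overwritten.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .phantom import AcquisitionRealization, GradientScheme
from .tensorfit import DiffusivityMaps

__all__ = [
    "FormatError",
    "read_dwi",
    "write_dwi",
    "write_maps",
    "write_results_csv",
    "write_report_json",
    "config_hash",
    "provenance_block",
]

UNIT_NORM_TOL = 1e-3


class FormatError(ValueError):
    """A file did not match its expected format or contract."""


def _check_new(path: Path, overwrite: bool):
    if path.exists() and not overwrite:
        raise FileExistsError(f"refusing to overwrite {path}")


def read_dwi(nifti_path, bval_path, bvec_path) -> AcquisitionRealization:
    """Load a 4D DWI volume plus FSL-dialect bval/bvec into an acquisition.

    Validates volume/entry counts and unit-norm weighted directions
    (tolerance 1e-3). Echo/diffusion times are not stored in FSL tables and
    are left unset.
    """
    nifti_path, bval_path, bvec_path = Path(nifti_path), Path(bval_path), Path(bvec_path)
    try:
        img = nib.load(nifti_path)
    except Exception as exc:
        raise FormatError(f"unreadable NIfTI header in {nifti_path}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{nifti_path} is not 4D")
    bvals = np.loadtxt(bval_path, ndmin=1)
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] != 3:
        raise FormatError(f"{bvec_path}: expected 3 rows (x, y, z), got {bvecs.shape[0]}")
    if len(bvals) != data.shape[3] or bvecs.shape[1] != data.shape[3]:
        raise FormatError(
            f"volume count mismatch: {nifti_path} has {data.shape[3]} volumes, "
            f"{bval_path} has {len(bvals)} entries, {bvec_path} has {bvecs.shape[1]}"
        )
    directions = bvecs.T
    weighted = bvals > 0
    norms = np.linalg.norm(directions[weighted], axis=1)
    if np.any(np.abs(norms - 1.0) > UNIT_NORM_TOL):
        raise FormatError(
            f"{bvec_path}: weighted directions deviate from unit norm beyond "
            f"tolerance {UNIT_NORM_TOL}"
        )
    directions = directions.copy()
    directions[weighted] /= norms[:, None]
    n_axes = len(np.unique(np.round(directions[weighted], 6), axis=0))
    scheme = GradientScheme(
        directions=directions, bvalues=bvals, n_axes=n_axes, averages=1,
        label=nifti_path.stem,
    )
    return AcquisitionRealization(
        signals=data, scheme=scheme, snr_b0=float("nan"), affine=img.affine,
    )


def write_dwi(acq: AcquisitionRealization, out_dir, stem: str = "dwi", overwrite: bool = False) -> dict:
    """Write an acquisition as NIfTI-1 + .bval/.bvec (FSL dialect)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {k: out_dir / f"{stem}{ext}" for k, ext in
             [("nii", ".nii.gz"), ("bval", ".bval"), ("bvec", ".bvec")]}
    for p in paths.values():
        _check_new(p, overwrite)
    affine = acq.affine if acq.affine is not None else np.eye(4)
    img = nib.Nifti1Image(acq.signals.astype(np.float32), affine)
    img.set_qform(affine, code=1)
    img.set_sform(affine, code=1)
    nib.save(img, paths["nii"])
    scheme = acq.scheme
    reps = 1 if acq.averaged else scheme.averages
    bvals = np.tile(scheme.bvalues, reps)
    bvecs = np.tile(scheme.directions, (reps, 1)).T
    np.savetxt(paths["bval"], bvals[None, :], fmt="%.1f")
    np.savetxt(paths["bvec"], bvecs, fmt="%.8f")
    return {k: str(p) for k, p in paths.items()}


def write_maps(maps: DiffusivityMaps, out_dir, overwrite: bool = False) -> dict:
    """Write dxx/dyy/dzz (and FA/MD where present) as NIfTI-1 volumes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = maps.affine if maps.affine is not None else np.eye(4)
    volumes = {"dxx": maps.dxx, "dyy": maps.dyy, "dzz": maps.dzz,
               "mask": maps.fit_mask.astype(np.uint8)}
    if maps.fa is not None:
        volumes["fa"] = maps.fa
    if maps.md is not None:
        volumes["md"] = maps.md
    written = {}
    for name, vol in volumes.items():
        p = out_dir / f"{name}.nii.gz"
        _check_new(p, overwrite)
        img = nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine)
        img.set_qform(affine, code=1)
        img.set_sform(affine, code=1)
        nib.save(img, p)
        written[name] = str(p)
    return written


def canonical_json(obj) -> str:
    """Canonical JSON used for hashing configs (sorted keys, no whitespace)."""

    def default(o):
        if is_dataclass(o) and not isinstance(o, type):
            return asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, Path):
            return str(o)
        return str(o)

    return json.dumps(obj, sort_keys=True, separators=(",", ":"), default=default)


def config_hash(config) -> str:
    """SHA-256 over the canonicalized configuration."""
    return hashlib.sha256(canonical_json(config).encode()).hexdigest()


def provenance_block(seed, config) -> dict:
    return {"package_version": __version__, "seed": seed, "config_sha256": config_hash(config)}


def write_results_csv(df: pd.DataFrame, path, overwrite: bool = False,
                      float_format: str = "%.4f") -> str:
    """Write a tidy result table; index values are rounded to 4 decimals in
    the CSV (full precision stays in the API)."""
    path = Path(path)
    _check_new(path, overwrite)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=float_format)
    return str(path)


def write_report_json(report: dict, path, seed, config, overwrite: bool = False) -> str:
    path = Path(path)
    _check_new(path, overwrite)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"provenance": provenance_block(seed, config), **report}
    path.write_text(json.dumps(payload, indent=2, default=lambda o: str(o)))
    return str(path)
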