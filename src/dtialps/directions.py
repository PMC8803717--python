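"""Deterministic diffusion-gradient direction sets.

The 3-axis set is the orthogonal scanner axes (x, y, z). The 12- and
30-direction sets are spherical-Fibonacci hemisphere point sets: generated by
a closed formula, approximately uniform under the antipodal (line) metric,
and frozen here so every run samples the identical scheme. Vendors ship their
own proprietary tables; for this package only the direction *count* matters,
so a documented reproducible set is used instead.
"""

from __future__ import annotations

import numpy as np

#: Minimum pairwise line angle (degrees, antipodally symmetrized) of each
#: generated set, computed once by brute force and frozen. Tests re-derive
#: these exhaustively.
MIN_LINE_ANGLE_DEG = {12: 26.3, 30: 13.8}

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """Return ``n`` unit vectors on the upper hemisphere (z > 0).

    Points follow the spherical-Fibonacci lattice: z_i = (i + 1/2)/n and
    azimuth i times the golden angle, giving near-uniform area coverage.
    """
    i = np.arange(n)
    z = (i + 0.5) / n
    phi = i * GOLDEN_ANGLE
    r = np.sqrt(1.0 - z * z)
    pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def direction_set(n_axes: int) -> np.ndarray:
    """The package's frozen direction set for a given axis count.

    ``n_axes = 3`` returns the identity axes (the orthogonal-DWI scheme);
    12 and 30 return the Fibonacci hemisphere sets.
    """
    if n_axes == 3:
        return np.eye(3)
    if n_axes in (12, 30):
        return fibonacci_hemisphere(n_axes)
    raise ValueError(f"unsupported axis count {n_axes}; expected 3, 12 or 30")


def min_pairwise_line_angle_deg(directions: np.ndarray) -> float:
    """Brute-force minimum angle (degrees) between any two direction lines."""
    g = np.asarray(directions, dtype=float)
    dots = np.abs(g @ g.T)
    np.fill_diagonal(dots, 0.0)
    return float(np.degrees(np.arccos(np.clip(dots.max(), -1.0, 1.0))))
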