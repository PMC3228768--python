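"""Candidate target directions over the frontal hemisphere.

The localization model treats target direction as a discrete hypothesis
space: a set of azimuth/elevation positions distributed approximately
uniformly (equal-area) over the frontal hemisphere.  Azimuth is positive to
the right, elevation positive upward, both in degrees in [-90, +90].  The
unit-vector convention is ``(forward, right, up)`` with

    forward = cos(el) cos(az),  right = cos(el) sin(az),  up = sin(el)

so the frontal hemisphere is the set with forward component >= 0.  All
rotations and distance computations are done on unit vectors to avoid pole
artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Direction",
    "DirectionGrid",
    "make_direction_grid",
    "lambert_project",
    "great_circle_distance",
    "to_unit_vectors",
    "from_unit_vectors",
]

#: golden angle in radians, used by the spiral grid
_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class Direction:
    """A single target direction (degrees; azimuth right-positive, elevation up-positive)."""

    azimuth: float
    elevation: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.azimuth <= 90.0 and -90.0 <= self.elevation <= 90.0):
            raise ValueError(
                f"direction ({self.azimuth}, {self.elevation}) outside the frontal hemisphere"
            )


def to_unit_vectors(azimuth_deg, elevation_deg) -> np.ndarray:
    """Convert azimuth/elevation (degrees) to unit vectors, shape (..., 3) as (forward, right, up)."""
    az, el = np.broadcast_arrays(
        np.asarray(azimuth_deg, dtype=float), np.asarray(elevation_deg, dtype=float)
    )
    az, el = np.deg2rad(az), np.deg2rad(el)
    return np.stack(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)], axis=-1
    )


def from_unit_vectors(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`to_unit_vectors`; returns (azimuth_deg, elevation_deg)."""
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    v = v / norm
    el = np.rad2deg(np.arcsin(np.clip(v[..., 2], -1.0, 1.0)))
    az = np.rad2deg(np.arctan2(v[..., 1], v[..., 0]))
    return az, el


@dataclass(frozen=True)
class DirectionGrid:
    """An ordered set of candidate directions (the hypothesis space).

    Attributes
    ----------
    azimuth_deg, elevation_deg:
        1-D arrays of equal length, one entry per direction.
    """

    azimuth_deg: np.ndarray
    elevation_deg: np.ndarray

    def __post_init__(self) -> None:
        az = np.atleast_1d(np.asarray(self.azimuth_deg, dtype=float))
        el = np.atleast_1d(np.asarray(self.elevation_deg, dtype=float))
        if az.shape != el.shape or az.ndim != 1:
            raise ValueError("azimuth and elevation must be 1-D arrays of equal length")
        object.__setattr__(self, "azimuth_deg", az)
        object.__setattr__(self, "elevation_deg", el)

    @property
    def count(self) -> int:
        return self.azimuth_deg.size

    def __len__(self) -> int:
        return self.count

    def __getitem__(self, i: int) -> Direction:
        return Direction(float(self.azimuth_deg[i]), float(self.elevation_deg[i]))

    @property
    def unit_vectors(self) -> np.ndarray:
        """(n, 3) array of unit vectors for all directions."""
        return to_unit_vectors(self.azimuth_deg, self.elevation_deg)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "direction_id": np.arange(self.count),
                "azimuth_deg": self.azimuth_deg,
                "elevation_deg": self.elevation_deg,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def off_axis_angle_deg(self) -> np.ndarray:
        """Great-circle angle of every direction from the forward axis (0, 0)."""
        return great_circle_distance(
            self.azimuth_deg, self.elevation_deg, 0.0, 0.0
        )


def make_direction_grid(n: int) -> DirectionGrid:
    """Build a deterministic, approximately equal-area grid of ``n`` directions.

    Uses a Fibonacci (golden-angle) spiral restricted to the frontal
    hemisphere: the forward direction-cosine is stratified uniformly in
    (0, 1) — equal-area by the Archimedes projection — and successive points
    advance by the golden angle around the forward axis.

    Parameters
    ----------
    n:
        Number of directions; the returned grid has exactly ``n`` points.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError(f"grid size must be a positive integer, got {n!r}")
    if n == 1:
        return DirectionGrid(np.zeros(1), np.zeros(1))
    i = np.arange(n)
    forward = (i + 0.5) / n  # uniform in (0, 1): equal-area on the hemisphere
    r = np.sqrt(1.0 - forward**2)
    phi = i * _GOLDEN_ANGLE
    v = np.stack([forward, r * np.cos(phi), r * np.sin(phi)], axis=-1)
    az, el = from_unit_vectors(v)
    return DirectionGrid(az, el)


def lambert_project(azimuth_deg, elevation_deg) -> tuple[np.ndarray, np.ndarray]:
    """Lambert azimuthal equal-area projection centred on the forward axis.

    Maps (0, 0) to the origin; the frontal hemisphere fills the disk of
    radius sqrt(2).  Solid angle on the sphere is proportional to planar
    area, which makes the projection the natural canvas for entropy maps.

    Returns planar coordinates (x, y): x increases to the right, y upward.
    """
    v = to_unit_vectors(azimuth_deg, elevation_deg)
    forward = v[..., 0]
    if np.any(forward < -1e-12):
        raise ValueError("direction outside the frontal hemisphere")
    k = np.sqrt(2.0 / (1.0 + np.clip(forward, 0.0, None)))
    return k * v[..., 1], k * v[..., 2]


def great_circle_distance(az1, el1, az2, el2) -> np.ndarray:
    """Great-circle angle in degrees between direction pairs (broadcasting)."""
    v1 = to_unit_vectors(az1, el1)
    v2 = to_unit_vectors(az2, el2)
    dot = np.clip(np.sum(v1 * v2, axis=-1), -1.0, 1.0)
    return np.rad2deg(np.arccos(dot))


def nearest_neighbour_spacing_cv(grid: DirectionGrid) -> float:
    """Coefficient of variation of nearest-neighbour great-circle spacing.

    A grid-quality diagnostic: values well below 0.25 indicate an
    approximately equal-area point set.
    """
    v = grid.unit_vectors
    dot = np.clip(v @ v.T, -1.0, 1.0)
    np.fill_diagonal(dot, -1.0)
    nn = np.rad2deg(np.arccos(dot.max(axis=1)))
    return float(np.std(nn) / np.mean(nn))
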