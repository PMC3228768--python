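"""Directional sensitivity patterns and pinna motion.

The expected received level for a target direction is set by the combined
emission directionality and the hearing directionality of each ear (the
augmented head-related transfer function).  This module provides

* a parametric beam generator — a smooth, single-lobed Gaussian directivity
  (optionally with a side lobe) standing in for numerically simulated or
  measured patterns;
* a loader for externally supplied directivity grids (CSV);
* rigid rotation of a pattern, which is how pinna motion is modelled: the
  hearing directionality is rotated as a whole while the emission pattern
  stays fixed;
* pinna trajectories: each ear sweeps an oblique arc (default ±15° in both
  azimuth and elevation) during echo reception, the two ears in anti-phase
  (one moves up while the other moves down).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

from .directions import (
    from_unit_vectors,
    great_circle_distance,
    lambert_project,
    make_direction_grid,
    to_unit_vectors,
)

__all__ = [
    "DirectivityPattern",
    "ParametricBeam",
    "GriddedPattern",
    "RotatedPattern",
    "PinnaTrajectory",
    "make_parametric_beam",
    "load_directivity",
    "rotate_pattern",
    "make_trajectory",
    "export_directivity",
]


class DirectivityPattern:
    """Base class: a gain field (dB, peak-normalized to 0) over direction.

    Subclasses implement :meth:`gain_db` accepting array azimuth/elevation
    in degrees and returning gain in dB relative to the pattern peak.
    """

    #: nominal frequency the pattern represents (metadata only)
    frequency_khz: float = 75.0

    def gain_db(self, azimuth_deg, elevation_deg) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, azimuth_deg, elevation_deg) -> np.ndarray:
        return self.gain_db(azimuth_deg, elevation_deg)


def _rotation_matrix(delta_az_deg: float, delta_el_deg: float) -> np.ndarray:
    """Rotation taking the forward axis to (delta_az, delta_el).

    Azimuth rotation about the up axis first, then elevation rotation about
    the right axis, in the (forward, right, up) frame.
    """
    a = np.deg2rad(delta_az_deg)
    e = np.deg2rad(delta_el_deg)
    ca, sa, ce, se = np.cos(a), np.sin(a), np.cos(e), np.sin(e)
    rz = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    ry = np.array([[ce, 0.0, -se], [0.0, 1.0, 0.0], [se, 0.0, ce]])
    return ry @ rz


class ParametricBeam(DirectivityPattern):
    """Circular Gaussian lobe in off-axis angle, optional raised side lobe.

    The main lobe is ``-3 (psi / psi_hp)**2`` dB at off-axis angle ``psi``
    where ``psi_hp = beamwidth / 2`` is the half-power half-angle, so the
    gain is exactly -3 dB at the half-power beamwidth.  An optional side
    lobe is a second Gaussian bump centred ``sidelobe_offset`` degrees off
    axis at ``sidelobe_level`` dB; the two lobes combine by maximum.
    """

    def __init__(
        self,
        beamwidth_deg: float,
        boresight_az_deg: float = 0.0,
        boresight_el_deg: float = 0.0,
        sidelobe_level_db: float | None = None,
        sidelobe_offset_deg: float = 60.0,
        sidelobe_width_deg: float | None = None,
        frequency_khz: float = 75.0,
    ) -> None:
        if beamwidth_deg <= 0:
            raise ValueError(f"beamwidth must be positive, got {beamwidth_deg}")
        if sidelobe_level_db is not None and sidelobe_level_db > 0:
            raise ValueError("sidelobe level must be <= 0 dB (peak-normalized)")
        self.beamwidth_deg = float(beamwidth_deg)
        self.boresight_az_deg = float(boresight_az_deg)
        self.boresight_el_deg = float(boresight_el_deg)
        self.sidelobe_level_db = sidelobe_level_db
        self.sidelobe_offset_deg = float(sidelobe_offset_deg)
        self.sidelobe_width_deg = float(
            sidelobe_width_deg if sidelobe_width_deg is not None else beamwidth_deg / 2
        )
        self.frequency_khz = float(frequency_khz)

    def gain_db(self, azimuth_deg, elevation_deg) -> np.ndarray:
        psi = great_circle_distance(
            azimuth_deg, elevation_deg, self.boresight_az_deg, self.boresight_el_deg
        )
        half = self.beamwidth_deg / 2.0
        main = -3.0 * (psi / half) ** 2
        if self.sidelobe_level_db is None:
            return main
        side_half = self.sidelobe_width_deg / 2.0
        side = self.sidelobe_level_db - 3.0 * (
            (psi - self.sidelobe_offset_deg) / side_half
        ) ** 2
        return np.maximum(main, side)


class GriddedPattern(DirectivityPattern):
    """Directivity defined by interpolation on a loaded (az, el, gain) grid.

    Interpolation is linear on the Lambert equal-area plane with
    nearest-node fallback outside the convex hull; gains are re-normalized
    so the peak over the loaded nodes is 0 dB.
    """

    def __init__(
        self,
        azimuth_deg: np.ndarray,
        elevation_deg: np.ndarray,
        gain_db_values: np.ndarray,
        frequency_khz: float = 75.0,
    ) -> None:
        az = np.asarray(azimuth_deg, dtype=float)
        el = np.asarray(elevation_deg, dtype=float)
        g = np.asarray(gain_db_values, dtype=float)
        if az.size == 0:
            raise ValueError("empty directivity grid")
        if not np.all(np.isfinite(g)):
            raise ValueError("non-finite gains in directivity grid")
        g = g - g.max()  # peak-normalize
        x, y = lambert_project(az, el)
        pts = np.column_stack([x, y])
        self._linear = LinearNDInterpolator(pts, g)
        self._nearest = NearestNDInterpolator(pts, g)
        self.node_azimuth_deg = az
        self.node_elevation_deg = el
        self.node_gain_db = g
        self.frequency_khz = float(frequency_khz)

    def gain_db(self, azimuth_deg, elevation_deg) -> np.ndarray:
        # directions pushed behind the frontal hemisphere by a rotation are
        # clamped to the hemisphere boundary before nearest-node lookup
        v = to_unit_vectors(azimuth_deg, elevation_deg)
        v = np.atleast_2d(v)
        behind = v[..., 0] < 0.0
        if np.any(behind):
            v = v.copy()
            v[behind, 0] = 0.0
            v[behind] /= np.linalg.norm(v[behind], axis=-1, keepdims=True)
        az, el = from_unit_vectors(v)
        x, y = lambert_project(az, el)
        out = self._linear(x, y)
        miss = ~np.isfinite(out)
        if np.any(miss):
            out[miss] = self._nearest(x[miss], y[miss])
        shape = np.shape(np.broadcast(np.asarray(azimuth_deg), np.asarray(elevation_deg)))
        return out.reshape(shape) if shape else float(out[0])


class RotatedPattern(DirectivityPattern):
    """A pattern rigidly rotated by (delta_az, delta_el); shape preserved."""

    def __init__(self, base: DirectivityPattern, delta_az_deg: float, delta_el_deg: float) -> None:
        self.base = base
        self.delta_az_deg = float(delta_az_deg)
        self.delta_el_deg = float(delta_el_deg)
        self._inv = _rotation_matrix(delta_az_deg, delta_el_deg).T
        self.frequency_khz = base.frequency_khz

    def gain_db(self, azimuth_deg, elevation_deg) -> np.ndarray:
        v = to_unit_vectors(azimuth_deg, elevation_deg)
        az, el = from_unit_vectors(v @ self._inv.T)
        return self.base.gain_db(az, el)


def make_parametric_beam(
    beamwidth_deg: float,
    boresight_az_deg: float = 0.0,
    boresight_el_deg: float = 0.0,
    sidelobe_level_db: float | None = None,
    sidelobe_offset_deg: float = 60.0,
    **kwargs,
) -> ParametricBeam:
    """Convenience constructor for :class:`ParametricBeam`."""
    return ParametricBeam(
        beamwidth_deg,
        boresight_az_deg,
        boresight_el_deg,
        sidelobe_level_db,
        sidelobe_offset_deg,
        **kwargs,
    )


_REQUIRED_COLUMNS = ("azimuth_deg", "elevation_deg", "gain_db")


def load_directivity(path: str | Path, max_gap_deg: float = 20.0) -> GriddedPattern:
    """Load a directivity grid from CSV (columns azimuth_deg, elevation_deg, gain_db).

    The loaded pattern is peak-normalized to 0 dB.  Raises ``ValueError``
    if required columns are missing, the file is empty, or the node set
    leaves a frontal-hemisphere coverage gap larger than ``max_gap_deg``
    (great-circle distance from any probe direction to its nearest node).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty directivity file: {path}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"directivity file {path} missing columns: {missing}")
    if len(df) == 0:
        raise ValueError(f"empty directivity file: {path}")
    probe = make_direction_grid(200)
    d = great_circle_distance(
        probe.azimuth_deg[:, None],
        probe.elevation_deg[:, None],
        df["azimuth_deg"].to_numpy()[None, :],
        df["elevation_deg"].to_numpy()[None, :],
    )
    worst = float(d.min(axis=1).max())
    if worst > max_gap_deg:
        raise ValueError(
            f"directivity grid has coverage gaps up to {worst:.1f} deg "
            f"(threshold {max_gap_deg} deg)"
        )
    return GriddedPattern(
        df["azimuth_deg"].to_numpy(),
        df["elevation_deg"].to_numpy(),
        df["gain_db"].to_numpy(),
    )


def export_directivity(pattern: DirectivityPattern, path: str | Path, n: int = 2000) -> None:
    """Evaluate ``pattern`` on an equal-area grid and write the directivity CSV."""
    grid = make_direction_grid(n)
    pd.DataFrame(
        {
            "azimuth_deg": grid.azimuth_deg,
            "elevation_deg": grid.elevation_deg,
            "gain_db": pattern.gain_db(grid.azimuth_deg, grid.elevation_deg),
        }
    ).to_csv(path, index=False)


def rotate_pattern(
    pattern: DirectivityPattern, delta_az_deg: float, delta_el_deg: float
) -> DirectivityPattern:
    """Rigidly rotate a directivity pattern (the pinna-motion approximation)."""
    if abs(delta_az_deg) > 90 or abs(delta_el_deg) > 90:
        raise ValueError("rotation offsets must be within +/-90 degrees")
    if delta_az_deg == 0.0 and delta_el_deg == 0.0:
        return pattern
    return RotatedPattern(pattern, delta_az_deg, delta_el_deg)


@dataclass(frozen=True)
class PinnaTrajectory:
    """Rotation offsets of one pinna across the stroke positions of a sweep."""

    ear: str
    delta_az_deg: np.ndarray
    delta_el_deg: np.ndarray

    def __post_init__(self) -> None:
        if self.ear not in ("left", "right"):
            raise ValueError(f"ear must be 'left' or 'right', got {self.ear!r}")
        object.__setattr__(self, "delta_az_deg", np.asarray(self.delta_az_deg, float))
        object.__setattr__(self, "delta_el_deg", np.asarray(self.delta_el_deg, float))
        if self.delta_az_deg.shape != self.delta_el_deg.shape:
            raise ValueError("offset arrays must have equal length")

    @property
    def n_positions(self) -> int:
        return self.delta_az_deg.size


def make_trajectory(
    ear: str,
    arc_az_deg: float = 15.0,
    arc_el_deg: float = 15.0,
    n_positions: int = 100,
    azimuth_phase: str = "anti",
) -> PinnaTrajectory:
    """Linear pinna sweep between the arc endpoints.

    The right ear sweeps elevation from ``-arc_el`` up to ``+arc_el``; the
    left ear sweeps down over the same arc (anti-phase).  Azimuth follows
    the same anti-phase pairing by default; ``azimuth_phase='in'`` makes
    both ears sweep azimuth in the same sense (the sign convention for the
    azimuth component of the arc is not uniquely determined by reports of
    the motion, so both pairings are available).
    """
    if not isinstance(n_positions, (int, np.integer)) or n_positions < 1:
        raise ValueError(f"n_positions must be a positive integer, got {n_positions!r}")
    if n_positions == 1:
        return PinnaTrajectory(ear, np.zeros(1), np.zeros(1))
    up = np.linspace(-1.0, 1.0, n_positions)
    if ear == "right":
        el = arc_el_deg * up
        az = arc_az_deg * up
    elif ear == "left":
        el = -arc_el_deg * up
        az = (-arc_az_deg * up) if azimuth_phase == "anti" else (arc_az_deg * up)
    else:
        raise ValueError(f"ear must be 'left' or 'right', got {ear!r}")
    return PinnaTrajectory(ear, az, el)
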