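"""Binaural amplitude-modulation templates and glint sampling.

As the pinnae sweep through their stroke during echo reception, the gain of
each ear toward a fixed target direction changes, imposing a
direction-specific amplitude modulation on the received echo.  The expected
modulation at the two ears across stroke positions is the *template* for
that direction; localization is matching a received (sampled, noisy) level
vector against the stored template set.

A fluttering insect returns one amplitude-stable dominant glint per
wingbeat, so the receiver only observes the modulation at discrete glint
times: a flutter rate of f Hz during a call of duration D seconds yields
floor(f*D) glint samples per ear (1 to 10 for 20-200 Hz at 50 ms).  One
full ear stroke is taken to span one call duration, so template modulation
frequencies are naturally expressed in cycles per ear stroke and the
Nyquist limit of glint sampling is f*D/2 cycles per stroke.

Templates are normalized to zero mean over both ears and all stroke
positions; the overall echo strength is carried by a separate nuisance
parameter in the inference model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ahrtf import DirectivityPattern, PinnaTrajectory, rotate_pattern
from .directions import DirectionGrid

__all__ = [
    "BinauralTemplate",
    "TemplateSet",
    "GlintSchedule",
    "SampledTemplate",
    "build_templates",
    "make_glint_schedule",
    "glint_count",
    "sample_template",
    "sample_template_set",
    "template_dynamic_range",
    "template_spectrum",
    "nyquist_limit",
]


@dataclass(frozen=True)
class BinauralTemplate:
    """Expected modulation for one direction: 2 x n_positions dB matrix (L, R)."""

    direction_id: int
    levels_db: np.ndarray  # shape (2, n_positions), zero mean overall
    normalization_offset_db: float = 0.0

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels_db, dtype=float)
        if lv.ndim != 2 or lv.shape[0] != 2:
            raise ValueError("levels must have shape (2, n_positions)")
        if not np.all(np.isfinite(lv)):
            raise ValueError("template levels must be finite")
        object.__setattr__(self, "levels_db", lv)

    @property
    def n_positions(self) -> int:
        return self.levels_db.shape[1]


@dataclass(frozen=True)
class TemplateSet:
    """Templates for every direction of a grid: (n_dir, 2, n_positions) dB array."""

    grid: DirectionGrid
    levels_db: np.ndarray
    normalization_offsets_db: np.ndarray

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels_db, dtype=float)
        if lv.ndim != 3 or lv.shape[0] != self.grid.count or lv.shape[1] != 2:
            raise ValueError("levels must have shape (n_directions, 2, n_positions)")
        object.__setattr__(self, "levels_db", lv)
        object.__setattr__(
            self, "normalization_offsets_db", np.asarray(self.normalization_offsets_db, float)
        )

    @property
    def n_directions(self) -> int:
        return self.levels_db.shape[0]

    @property
    def n_positions(self) -> int:
        return self.levels_db.shape[2]

    def __len__(self) -> int:
        return self.n_directions

    def __getitem__(self, i: int) -> BinauralTemplate:
        return BinauralTemplate(
            i, self.levels_db[i], float(self.normalization_offsets_db[i])
        )

    def flattened(self) -> np.ndarray:
        """(n_dir, 2*n_positions) array: left-ear positions then right-ear positions."""
        return self.levels_db.reshape(self.n_directions, -1)

    def to_frame(self) -> pd.DataFrame:
        n_dir, _, n_pos = self.levels_db.shape
        idx = np.arange(n_dir).repeat(2 * n_pos)
        ear = np.tile(np.repeat(["left", "right"], n_pos), n_dir)
        pos = np.tile(np.arange(n_pos), 2 * n_dir)
        return pd.DataFrame(
            {
                "direction_id": idx,
                "azimuth_deg": self.grid.azimuth_deg[idx],
                "elevation_deg": self.grid.elevation_deg[idx],
                "ear": ear,
                "position_index": pos,
                "level_db": self.levels_db.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_templates(
    emission: DirectivityPattern,
    ear_left: DirectivityPattern,
    ear_right: DirectivityPattern,
    trajectory_left: PinnaTrajectory,
    trajectory_right: PinnaTrajectory,
    grid: DirectionGrid,
) -> TemplateSet:
    """Build zero-mean binaural templates for every grid direction.

    At stroke position j the expected received level (dB, up to the echo
    strength) toward direction theta is the emission gain at theta plus the
    gain of the rigidly rotated ear pattern at theta; the emission pattern
    does not move with the pinnae.  Each direction's 2 x n_positions matrix
    is then shifted to zero mean, the removed offset being recorded.
    """
    if trajectory_left.n_positions != trajectory_right.n_positions:
        raise ValueError("left and right trajectories must have the same length")
    n_pos = trajectory_left.n_positions
    az, el = grid.azimuth_deg, grid.elevation_deg
    emit = np.asarray(emission.gain_db(az, el), dtype=float)
    levels = np.empty((grid.count, 2, n_pos))
    for e, (pattern, traj) in enumerate(
        [(ear_left, trajectory_left), (ear_right, trajectory_right)]
    ):
        for j in range(n_pos):
            rot = rotate_pattern(pattern, traj.delta_az_deg[j], traj.delta_el_deg[j])
            levels[:, e, j] = emit + np.asarray(rot.gain_db(az, el), dtype=float)
    offsets = levels.reshape(grid.count, -1).mean(axis=1)
    levels -= offsets[:, None, None]
    return TemplateSet(grid, levels, offsets)


@dataclass(frozen=True)
class GlintSchedule:
    """Sample times of dominant glints within one call."""

    flutter_rate_hz: float
    call_duration_s: float
    sample_times_s: np.ndarray
    mode: str  # "regular" | "random"

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times_s, dtype=float)
        if t.size == 0:
            raise ValueError("schedule must contain at least one sample time")
        if np.any(t < 0) or np.any(t >= self.call_duration_s):
            raise ValueError("sample times must lie in [0, call_duration)")
        object.__setattr__(self, "sample_times_s", t)

    @property
    def n_samples(self) -> int:
        return self.sample_times_s.size


def glint_count(flutter_rate_hz: float, call_duration_s: float) -> int:
    """Number of dominant glints in one call: floor(f*D), at least 1."""
    return max(1, int(np.floor(flutter_rate_hz * call_duration_s + 1e-9)))


def make_glint_schedule(
    flutter_rate_hz: float,
    call_duration_s: float = 0.050,
    mode: str = "regular",
    rng: np.random.Generator | int | None = None,
) -> GlintSchedule:
    """Draw the glint sample times for one call.

    Regular mode: times ``t0 + i / f`` below the call duration, with the
    phase ``t0`` uniform on [0, 0.5/f).  Random mode: the same number of
    times as the regular schedule, drawn uniformly over the call and sorted.
    """
    if flutter_rate_hz <= 0 or call_duration_s <= 0:
        raise ValueError("flutter rate and call duration must be positive")
    if mode not in ("regular", "random"):
        raise ValueError(f"mode must be 'regular' or 'random', got {mode!r}")
    rng = np.random.default_rng(rng)
    period = 1.0 / flutter_rate_hz
    if mode == "regular":
        t0 = rng.uniform(0.0, 0.5 * period)
        times = t0 + period * np.arange(int(np.ceil(call_duration_s / period)) + 1)
        times = times[times < call_duration_s]
        if times.size == 0:  # call shorter than half a flutter period
            times = np.array([min(t0, np.nextafter(call_duration_s, 0.0))])
    else:
        k = glint_count(flutter_rate_hz, call_duration_s)
        times = np.sort(rng.uniform(0.0, call_duration_s, size=k))
    return GlintSchedule(flutter_rate_hz, call_duration_s, times, mode)


@dataclass(frozen=True)
class SampledTemplate:
    """Template levels at the glint times: left-ear samples then right-ear samples."""

    direction_id: int
    values_db: np.ndarray  # length 2k
    schedule: GlintSchedule

    def __post_init__(self) -> None:
        v = np.asarray(self.values_db, dtype=float)
        if v.size != 2 * self.schedule.n_samples:
            raise ValueError("sampled template length must be 2 x number of sample times")
        object.__setattr__(self, "values_db", v)


def _stroke_coordinates(schedule: GlintSchedule, n_positions: int) -> np.ndarray:
    # one full ear stroke spans one call duration
    if n_positions == 1:
        return np.zeros(schedule.n_samples)
    return schedule.sample_times_s / schedule.call_duration_s * (n_positions - 1)


def sample_template(template: BinauralTemplate, schedule: GlintSchedule) -> SampledTemplate:
    """Sample one template at the glint times (linear interpolation in dB)."""
    x = _stroke_coordinates(schedule, template.n_positions)
    pos = np.arange(template.n_positions)
    left = np.interp(x, pos, template.levels_db[0])
    right = np.interp(x, pos, template.levels_db[1])
    return SampledTemplate(template.direction_id, np.concatenate([left, right]), schedule)


def sample_template_set(templates: TemplateSet, schedule: GlintSchedule) -> np.ndarray:
    """Sample every template; returns (n_directions, 2k) with left samples first."""
    n_pos = templates.n_positions
    x = _stroke_coordinates(schedule, n_pos)
    lo = np.clip(np.floor(x).astype(int), 0, max(n_pos - 2, 0))
    frac = x - lo
    lv = templates.levels_db
    if n_pos == 1:
        sampled = np.repeat(lv, len(x), axis=2)
    else:
        sampled = lv[:, :, lo] * (1.0 - frac) + lv[:, :, lo + 1] * frac
    return sampled.reshape(templates.n_directions, -1)


def template_dynamic_range(template: BinauralTemplate | np.ndarray) -> float:
    """Dynamic range (max minus min level, dB) over both ears of one template."""
    lv = template.levels_db if isinstance(template, BinauralTemplate) else np.asarray(template)
    return float(lv.max() - lv.min())


def template_spectrum(templates: TemplateSet) -> tuple[np.ndarray, np.ndarray]:
    """Mean one-sided modulation magnitude spectrum of the templates.

    Each ear's stroke sequence is Fourier-transformed with orthonormal
    scaling and folded to one side preserving energy (so the sum of squared
    spectrum values equals the sum of squared samples).  Returns
    ``(frequencies, mean_magnitude)`` with frequency in cycles per ear
    stroke and the magnitude averaged over ears and directions.
    """
    n_pos = templates.n_positions
    seq = templates.levels_db.reshape(-1, n_pos)  # (n_dir*2, n_pos)
    spec = np.fft.rfft(seq, axis=1, norm="ortho")
    mag = np.abs(spec)
    fold = np.full(mag.shape[1], np.sqrt(2.0))
    fold[0] = 1.0
    if n_pos % 2 == 0:
        fold[-1] = 1.0
    mag *= fold
    freqs = np.arange(mag.shape[1], dtype=float)  # bin k = k cycles per stroke
    return freqs, mag.mean(axis=0)


def nyquist_limit(flutter_rate_hz: float, call_duration_s: float) -> float:
    """Highest template frequency (cycles per ear stroke) recoverable from glint samples.

    ``flutter_rate * call_duration`` glints per stroke sample the modulation,
    so frequencies up to half that count are representable.
    """
    if flutter_rate_hz <= 0 or call_duration_s <= 0:
        raise ValueError("flutter rate and call duration must be positive")
    return flutter_rate_hz * call_duration_s / 2.0
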