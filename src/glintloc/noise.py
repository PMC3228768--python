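"""Measurement model: amplitude noise covariance and echo simulation.

Received glint levels are modelled in the log (dB) domain.  The level
vector concatenates the k left-ear and k right-ear samples; within one echo
the amplitude noise is

* independent across glints (different wingbeat cycles),
* highly correlated between the two ears at the same glint (both ears see
  the same reflector fluctuation), with correlation ``rho_lr``,
* of equal standard deviation ``sigma`` dB on every sample.

System noise sets a detection floor: in the log domain additive system
noise acts approximately as a maximum operator, so received levels are
clipped from below at the floor (default 0 dB, making the echo-strength
parameter interpretable as a signal-to-noise ratio).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .templates import SampledTemplate

__all__ = ["NoiseSpec", "build_covariance", "simulate_measurement", "Measurement"]


@dataclass(frozen=True)
class NoiseSpec:
    """Per-sample amplitude noise SD (dB), left/right correlation, detection floor (dB)."""

    sigma_db: float = 1.5
    rho_lr: float = 0.9
    floor_db: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_db < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma_db}")
        if not (0.0 <= self.rho_lr < 1.0):
            raise ValueError(f"rho_lr must lie in [0, 1), got {self.rho_lr}")


def build_covariance(k: int, spec: NoiseSpec) -> np.ndarray:
    """Covariance of the 2k-sample level vector (left samples then right samples).

    Diagonal ``sigma**2``; entries (i, k+i) equal ``rho_lr * sigma**2``
    (same glint, opposite ears); every other off-diagonal is zero.  Positive
    definite for ``rho_lr < 1`` and ``sigma > 0``.
    """
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ValueError(f"k must be a positive integer, got {k!r}")
    s2 = spec.sigma_db**2
    cov = np.eye(2 * k) * s2
    idx = np.arange(k)
    cov[idx, k + idx] = spec.rho_lr * s2
    cov[k + idx, idx] = spec.rho_lr * s2
    return cov


@dataclass(frozen=True)
class Measurement:
    """A received level vector with its generating truth attached."""

    values_db: np.ndarray
    direction_id: int
    echo_strength_db: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values_db", np.asarray(self.values_db, dtype=float))


def _correlated_noise(
    k: int, spec: NoiseSpec, rng: np.random.Generator, size: tuple[int, ...] = ()
) -> np.ndarray:
    """Draw N(0, Sigma) noise of shape (*size, 2k) using the pairwise structure.

    Each left/right pair at one glint is a bivariate normal with correlation
    rho_lr; pairs are independent, which reproduces the block covariance
    without a 2k x 2k factorization.
    """
    zl = rng.standard_normal(size + (k,))
    zr = rng.standard_normal(size + (k,))
    rho = spec.rho_lr
    left = zl
    right = rho * zl + np.sqrt(1.0 - rho**2) * zr
    return spec.sigma_db * np.concatenate([left, right], axis=-1)


def simulate_measurement(
    sampled: SampledTemplate | np.ndarray,
    echo_strength_db: float,
    spec: NoiseSpec,
    rng: np.random.Generator | int | None = None,
    direction_id: int | None = None,
) -> Measurement:
    """Simulate one received level vector.

    ``values = max(floor, template + A + noise)`` elementwise, with noise
    drawn from the structured covariance of :func:`build_covariance`.
    """
    rng = np.random.default_rng(rng)
    if isinstance(sampled, SampledTemplate):
        base = sampled.values_db
        did = sampled.direction_id if direction_id is None else direction_id
    else:
        base = np.asarray(sampled, dtype=float)
        did = -1 if direction_id is None else direction_id
    k = base.size // 2
    noise = _correlated_noise(k, spec, rng)
    values = np.maximum(spec.floor_db, base + echo_strength_db + noise)
    return Measurement(values, did, float(echo_strength_db))


def simulate_measurement_batch(
    sampled_matrix: np.ndarray,
    echo_strengths_db: np.ndarray,
    spec: NoiseSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate one measurement per (direction, strength) pair.

    ``sampled_matrix`` is (n_dir, 2k); returns (n_dir, n_strengths, 2k).
    """
    n_dir, two_k = sampled_matrix.shape
    k = two_k // 2
    n_a = len(echo_strengths_db)
    noise = _correlated_noise(k, spec, rng, size=(n_dir, n_a))
    mean = sampled_matrix[:, None, :] + np.asarray(echo_strengths_db, float)[None, :, None]
    return np.maximum(spec.floor_db, mean + noise)
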