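"""Geometric noise schedules for denoising score matching and annealing."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NoiseSchedule", "geometric_schedule"]


@dataclass(frozen=True)
class NoiseSchedule:
    """Strictly decreasing geometric sequence of noise scales sigma_1 > ... > sigma_L.

    The largest scale should be on the order of the data scale (the slices
    are z-normalized, so ~1) and the smallest sets the residual noise floor
    of the annealed sampler.
    """

    sigmas: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.sigmas, dtype=float)
        object.__setattr__(self, "sigmas", s)
        if s.ndim != 1 or len(s) < 2:
            raise ValueError("schedule needs at least two levels")
        if s[-1] <= 0:
            raise ValueError("all noise scales must be positive")
        if not np.all(np.diff(s) < 0):
            raise ValueError("noise scales must be strictly decreasing")
        ratios = s[1:] / s[:-1]
        if np.ptp(ratios) > 1e-9:
            raise ValueError("schedule must be geometric (constant ratio)")

    @property
    def L(self) -> int:
        return len(self.sigmas)

    @property
    def sigma_max(self) -> float:
        return float(self.sigmas[0])

    @property
    def sigma_min(self) -> float:
        return float(self.sigmas[-1])

    def __iter__(self):
        return iter(self.sigmas)

    def to_dict(self) -> dict:
        return {"sigmas": self.sigmas.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseSchedule":
        return cls(sigmas=np.asarray(d["sigmas"], dtype=float))


def geometric_schedule(
    sigma_max: float = 1.0, sigma_min: float = 0.01, n_levels: int = 10
) -> NoiseSchedule:
    """Default schedule: L geometric levels from sigma_max down to sigma_min."""
    if not (0 < sigma_min < sigma_max):
        raise ValueError("need 0 < sigma_min < sigma_max")
    return NoiseSchedule(np.geomspace(sigma_max, sigma_min, n_levels))
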