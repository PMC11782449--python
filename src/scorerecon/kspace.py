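"""Cartesian k-space forward model, vertical-line undersampling, zero-fill baseline.

Conventions (the single supported dialect):

* the spectrum is **centered** — the zero-frequency coefficient sits at the
  grid center (``fftshift`` applied after the transform);
* the transform is **orthonormal** (``norm="ortho"``), so Parseval holds
  exactly and forward/inverse compose to the identity;
* one k-space "line" is one full column of the centered spectrum (a
  phase-encode line); undersampling always removes whole columns and never
  rows ("vertical orientation").

The acceleration factor R is the ratio of full to acquired lines: a mask at
R keeps ``round(n_columns / R)`` columns (minimum 1), so at R = 5 on a
384-column grid 77 lines are kept and 80% are deleted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "SamplingMask",
    "KSpaceMeasurement",
    "forward_fourier",
    "inverse_fourier",
    "make_cartesian_mask",
    "undersample",
    "zero_fill_reconstruct",
    "save_mask_json",
    "load_mask_json",
    "save_measurement_hdf5",
    "load_measurement_hdf5",
]


@dataclass(frozen=True)
class SamplingMask:
    """Per-column keep/delete pattern for vertical-line Cartesian undersampling."""

    keep: np.ndarray  # boolean, one entry per k-space column
    R: float
    seed: int
    orientation: str = "vertical"

    def __post_init__(self):
        keep = np.asarray(self.keep, dtype=bool)
        object.__setattr__(self, "keep", keep)
        if keep.ndim != 1:
            raise ValueError("keep must be a 1-D boolean vector")
        if self.orientation != "vertical":
            raise ValueError("only vertical-line masks are supported")
        n_kept = int(keep.sum())
        if n_kept < 1:
            raise ValueError("a mask must keep at least one column")
        expected = max(1, int(round(len(keep) / self.R)))
        if n_kept != expected:
            raise ValueError(
                f"mask keeps {n_kept} columns but R={self.R} on {len(keep)} "
                f"columns requires {expected}"
            )

    @property
    def n_columns(self) -> int:
        return len(self.keep)

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    @property
    def deleted_fraction(self) -> float:
        return 1.0 - self.n_kept / self.n_columns


@dataclass(frozen=True)
class KSpaceMeasurement:
    """Observed data y = M . F(x): a centered spectrum zeroed on deleted columns."""

    grid: np.ndarray  # 2-D complex, centered
    mask: SamplingMask

    def __post_init__(self):
        if self.grid.ndim != 2:
            raise ValueError("measurement grid must be 2-D")
        if self.grid.shape[1] != self.mask.n_columns:
            raise ValueError("mask length must equal number of k-space columns")
        if np.any(self.grid[:, ~self.mask.keep] != 0):
            raise ValueError("deleted columns must be exactly zero")

    @property
    def shape(self):
        return self.grid.shape


def forward_fourier(image: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2-D DFT of a square real (or complex) image."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("input must be 2-D")
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(image), norm="ortho"))


def inverse_fourier(kspace: np.ndarray) -> np.ndarray:
    """Inverse of :func:`forward_fourier`; returns a complex image."""
    kspace = np.asarray(kspace)
    if kspace.ndim != 2:
        raise ValueError("input must be 2-D")
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(kspace), norm="ortho"))


def make_cartesian_mask(
    n_columns: int, R: float, seed: int, keep_center: int = 0
) -> SamplingMask:
    """Draw a vertical-line mask keeping ``round(n_columns / R)`` random columns.

    Kept columns are uniformly random distinct positions.  ``keep_center``
    forces that many central (low-frequency) columns to be retained before
    the random draw; the default is 0 — purely random positions, no
    autocalibration band.
    """
    if n_columns < 1:
        raise ValueError("n_columns must be >= 1")
    if R < 1:
        raise ValueError(f"acceleration factor must be >= 1, got {R}")
    n_keep = max(1, int(round(n_columns / R)))
    if keep_center > n_keep:
        raise ValueError("keep_center cannot exceed the kept-column budget")
    keep = np.zeros(n_columns, dtype=bool)
    center = n_columns // 2
    if keep_center:
        lo = center - keep_center // 2
        keep[lo : lo + keep_center] = True
    rng = np.random.default_rng(np.random.PCG64(seed))
    remaining = np.flatnonzero(~keep)
    extra = rng.choice(remaining, size=n_keep - int(keep.sum()), replace=False)
    keep[extra] = True
    return SamplingMask(keep=keep, R=float(R), seed=seed)


def undersample(kspace: np.ndarray, mask: SamplingMask) -> KSpaceMeasurement:
    """Zero the deleted columns of a centered spectrum; kept columns pass unchanged."""
    kspace = np.asarray(kspace, dtype=complex)
    if kspace.ndim != 2 or kspace.shape[1] != mask.n_columns:
        raise ValueError(
            f"k-space shape {kspace.shape} incompatible with mask of "
            f"{mask.n_columns} columns"
        )
    grid = kspace.copy()
    grid[:, ~mask.keep] = 0
    return KSpaceMeasurement(grid=grid, mask=mask)


def zero_fill_reconstruct(
    measurement: KSpaceMeasurement, output: str = "real"
) -> np.ndarray:
    """Inverse transform of the zero-filled spectrum — the artifact baseline.

    ``output`` selects the real part (default) or the magnitude of the
    complex inverse transform.
    """
    img = inverse_fourier(measurement.grid)
    if output == "real":
        return img.real
    if output == "magnitude":
        return np.abs(img)
    raise ValueError(f"unknown output mode {output!r}")


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def save_mask_json(mask: SamplingMask, path: str | Path) -> None:
    payload = {
        "n_columns": mask.n_columns,
        "R": mask.R,
        "seed": mask.seed,
        "orientation": mask.orientation,
        "keep": [int(i) for i in np.flatnonzero(mask.keep)],
    }
    Path(path).write_text(json.dumps(payload))


def load_mask_json(path: str | Path) -> SamplingMask:
    payload = json.loads(Path(path).read_text())
    keep = np.zeros(payload["n_columns"], dtype=bool)
    keep[payload["keep"]] = True
    return SamplingMask(keep=keep, R=payload["R"], seed=payload["seed"])


def save_measurement_hdf5(measurement: KSpaceMeasurement, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("grid", data=measurement.grid)
        f.create_dataset("keep", data=measurement.mask.keep)
        f.attrs["R"] = measurement.mask.R
        f.attrs["seed"] = measurement.mask.seed


def load_measurement_hdf5(path: str | Path) -> KSpaceMeasurement:
    with h5py.File(path, "r") as f:
        grid = f["grid"][()]
        mask = SamplingMask(
            keep=f["keep"][()], R=float(f.attrs["R"]), seed=int(f.attrs["seed"])
        )
    return KSpaceMeasurement(grid=grid, mask=mask)
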