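"""Seeded breast-MRI-like phantom volumes and cohort fixtures.

Clinical DCE breast-MRI data cannot be redistributed, so every downstream
stage of the pipeline (k-space undersampling, score-prior training, Langevin
reconstruction, metric evaluation) is exercised on synthetic phantoms that
reproduce the *statistical* structure of the real data: a smooth
breast-shaped envelope, band-limited internal texture, a handful of sharp
elliptical focal structures, and two contrast classes (T1-like vs T2-like)
that differ by a contrast inversion of the texture compartment.

The cohort generator mirrors the study-accounting flow of a retrospective
screening cohort: a table of studies, a fraction lacking the T2 sequence,
an eligibility filter that drops them, and a train/test split of the
remainder.

Every function is a pure function of its arguments and seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DegenerateInputError

__all__ = [
    "SequenceClass",
    "PhantomVolume",
    "ImageSlice",
    "generate_phantom",
    "generate_cohort",
    "apply_eligibility_filter",
    "assign_split",
    "slice_volume",
    "znormalize",
    "save_volume_nifti",
    "load_volume_nifti",
    "save_cohort_csv",
    "load_cohort_csv",
    "export_slices_hdf5",
]

#: Version tag of the phantom recipe.  Bump whenever the construction below
#: changes, so that archived fixtures are never silently regenerated
#: differently.
PHANTOM_RECIPE_VERSION = 1

COHORT_COLUMNS = ["study_id", "patient_id", "has_t2", "split"]


class SequenceClass(enum.Enum):
    """MRI contrast class used as a conditioning label for the prior."""

    T1 = 0
    T2 = 1


@dataclass(frozen=True)
class PhantomVolume:
    """A 3-D synthetic volume standing in for one breast MRI examination.

    Axes are ordered (z, y, x); in-plane dimensions are square.
    """

    voxels: np.ndarray
    sequence_class: SequenceClass
    study_id: str
    seed: int

    def __post_init__(self):
        v = self.voxels
        if v.ndim != 3:
            raise ValueError("voxels must be 3-D (z, y, x)")
        if v.shape[1] != v.shape[2]:
            raise ValueError("in-plane dimensions must be square")
        if v.shape[0] < 3:
            raise ValueError("depth must be at least 3")
        if not np.all(np.isfinite(v)):
            raise ValueError("voxel intensities must be finite")

    @property
    def depth(self) -> int:
        return self.voxels.shape[0]

    @property
    def size(self) -> int:
        return self.voxels.shape[1]


@dataclass(frozen=True)
class ImageSlice:
    """One z-normalized 2-D slice drawn from a volume."""

    pixels: np.ndarray
    sequence_class: SequenceClass
    study_id: str
    z_index: int

    def __post_init__(self):
        p = self.pixels
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("pixels must be a square 2-D grid")


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Gaussian-filtered white noise, rescaled to unit amplitude."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma=sigma, mode="nearest")
    peak = np.max(np.abs(sm))
    return sm / peak if peak > 0 else sm


def generate_phantom(
    seed: int,
    size: int = 64,
    depth: int = 8,
    sequence_class: SequenceClass = SequenceClass.T2,
    study_id: str | None = None,
) -> PhantomVolume:
    """Generate one seeded breast-like phantom volume.

    The recipe (version ``PHANTOM_RECIPE_VERSION``) composes, per volume:

    1. a smooth breast-shaped envelope — a soft-edged half-ellipsoid whose
       in-plane axes shrink slightly toward the top and bottom slices;
    2. a band-limited texture compartment (smoothed white noise) standing in
       for fibroglandular structure;
    3. 0–3 bright elliptical focal structures (sharp local features);
    4. a faint smooth intensity gradient so no slice is constant.

    T1-like and T2-like volumes at the same seed share all random geometry
    and differ by a contrast inversion of the texture compartment plus a
    brighter focal compartment in the T2-like class.

    Parameters
    ----------
    seed:
        Controls all randomness; identical arguments give bitwise-identical
        volumes.
    size:
        In-plane resolution (``size x size``); must be >= 16.  The native
        target of the emulated acquisition is 384, but any size down to the
        minimum is supported for desk-scale runs.
    depth:
        Number of z slices; must be >= 3 so three distinct slices can be
        drawn.
    sequence_class:
        T1-like or T2-like contrast.
    """
    if size < 16:
        raise ValueError(f"size must be >= 16, got {size}")
    if depth < 3:
        raise ValueError(f"depth must be >= 3, got {depth}")
    if study_id is None:
        study_id = f"PH{seed:08d}"

    # One stream for geometry shared by both classes: the class enters only
    # through the deterministic mixing weights below, never through rng
    # consumption order.
    rng = np.random.default_rng(np.random.PCG64(seed))

    zz = np.linspace(-1.0, 1.0, depth)[:, None, None]
    yy = np.linspace(-1.0, 1.0, size)[None, :, None]
    xx = np.linspace(-1.0, 1.0, size)[None, None, :]

    # Envelope: soft half-ellipsoid, chest wall at x = -1.
    cy = rng.uniform(-0.1, 0.1)
    ay = rng.uniform(0.55, 0.75)
    ax = rng.uniform(1.1, 1.4)
    z_taper = 1.0 - 0.25 * zz**2
    r2 = ((yy - cy) / (ay * z_taper)) ** 2 + ((xx + 1.0) / (ax * z_taper)) ** 2
    envelope = 1.0 / (1.0 + np.exp((r2 - 1.0) / 0.08))

    texture = _smooth_noise(rng, (depth, size, size), sigma=max(1.5, size / 24))

    focal = np.zeros((depth, size, size))
    n_focal = int(rng.integers(0, 4))
    for _ in range(n_focal):
        fz = rng.uniform(-0.5, 0.5)
        fy = rng.uniform(-0.4, 0.4) + cy
        fx = rng.uniform(-0.8, 0.1)
        rad = rng.uniform(0.05, 0.15)
        aspect = rng.uniform(0.6, 1.6)
        d2 = (
            ((zz - fz) / (2.5 * rad)) ** 2
            + ((yy - fy) / (rad * aspect)) ** 2
            + ((xx - fx) / (rad / aspect)) ** 2
        )
        focal += np.exp(-3.0 * d2)

    gradient = 0.05 * (0.6 * yy + 0.4 * xx + 0.2 * zz) + 0.05

    if sequence_class is SequenceClass.T1:
        tex_w, focal_w, base = 0.35, 0.5, 0.9
    else:  # T2-like: texture compartment inverted, focal lesions brighter
        tex_w, focal_w, base = -0.35, 0.9, 0.7

    voxels = envelope * (base + tex_w * texture + focal_w * focal) + gradient
    return PhantomVolume(
        voxels=voxels, sequence_class=sequence_class, study_id=study_id, seed=seed
    )


def generate_cohort(n_studies: int, n_missing_t2: int, seed: int) -> pd.DataFrame:
    """Generate a synthetic cohort table mirroring a study-accounting flowchart.

    Returns a DataFrame with columns ``study_id, patient_id, has_t2, split``;
    exactly ``n_missing_t2`` rows have ``has_t2 = False`` (positions drawn
    uniformly from the seed), and ``split`` starts as ``"unassigned"``.
    Patients may contribute several studies, as in a longitudinal screening
    cohort (roughly 1.9 studies per patient).
    """
    if n_studies < 0 or n_missing_t2 < 0:
        raise ValueError("counts must be non-negative")
    if n_missing_t2 > n_studies:
        raise ValueError("n_missing_t2 cannot exceed n_studies")
    rng = np.random.default_rng(np.random.PCG64(seed))
    n_patients = max(1, int(round(n_studies / 1.9))) if n_studies else 0
    patient_ids = (
        rng.integers(0, n_patients, size=n_studies) if n_studies else np.array([], dtype=int)
    )
    has_t2 = np.ones(n_studies, dtype=bool)
    if n_missing_t2:
        missing = rng.choice(n_studies, size=n_missing_t2, replace=False)
        has_t2[missing] = False
    return pd.DataFrame(
        {
            "study_id": [f"S{i:06d}" for i in range(n_studies)],
            "patient_id": [f"P{p:06d}" for p in patient_ids],
            "has_t2": has_t2,
            "split": "unassigned",
        }
    )


def apply_eligibility_filter(cohort: pd.DataFrame) -> pd.DataFrame:
    """Drop studies lacking a T2 sequence; row order is preserved.

    ``len(result) + (~cohort.has_t2).sum() == len(cohort)`` for every input.
    """
    _check_cohort(cohort)
    return cohort.loc[cohort["has_t2"]].reset_index(drop=True)


def assign_split(
    cohort: pd.DataFrame,
    n_train: int = 9549,
    n_eval: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Split an eligible cohort into train and test groups.

    ``n_train`` studies are drawn at random for training and the remainder
    is marked ``test``.  Of the test studies, ``n_eval`` are intended for
    the quantitative evaluation set (callers sample them with
    ``df[df.split == 'test'].head`` or a seeded choice); the split column
    records only train/test.  Only rows with ``has_t2 = True`` may receive
    a split.
    """
    _check_cohort(cohort)
    if not cohort["has_t2"].all():
        raise ValueError("assign_split expects an eligibility-filtered cohort")
    n = len(cohort)
    if n_train > n:
        raise ValueError(f"n_train={n_train} exceeds cohort size {n}")
    if n_eval > n - n_train:
        raise ValueError("n_eval exceeds the number of test studies")
    rng = np.random.default_rng(np.random.PCG64(seed))
    idx = rng.permutation(n)
    out = cohort.copy()
    out["split"] = "test"
    out.iloc[idx[:n_train], out.columns.get_loc("split")] = "train"
    return out


def znormalize(pixels: np.ndarray) -> np.ndarray:
    """Z-normalize an image to mean 0 and standard deviation 1.

    Uses the population (divide-by-N) standard deviation, so the mapping of
    ``[[0, 2], [0, 2]]`` is exactly ``[[-1, 1], [-1, 1]]``.  A constant
    image has no well-defined normalization and raises
    :class:`DegenerateInputError`.
    """
    pixels = np.asarray(pixels, dtype=float)
    sd = pixels.std()
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("constant (or non-finite) image cannot be z-normalized")
    return (pixels - pixels.mean()) / sd


def slice_volume(
    volume: PhantomVolume, n_slices: int = 3, seed: int = 0
) -> list[ImageSlice]:
    """Draw ``n_slices`` z-normalized 2-D slices at distinct random z positions.

    The z indices are sampled without replacement from ``[0, depth)``, so
    the standard three slices per volume are always distinct.
    """
    if n_slices > volume.depth:
        raise ValueError(
            f"n_slices={n_slices} exceeds volume depth {volume.depth}"
        )
    rng = np.random.default_rng(np.random.PCG64(seed))
    z_indices = rng.choice(volume.depth, size=n_slices, replace=False)
    return [
        ImageSlice(
            pixels=znormalize(volume.voxels[z]),
            sequence_class=volume.sequence_class,
            study_id=volume.study_id,
            z_index=int(z),
        )
        for z in z_indices
    ]


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def save_volume_nifti(volume: PhantomVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(
        np.asarray(volume.voxels, dtype=np.float32).transpose(2, 1, 0), np.eye(4)
    )
    img.header["descrip"] = f"{volume.study_id};{volume.sequence_class.name};seed={volume.seed}"
    nib.save(img, str(path))


def load_volume_nifti(
    path: str | Path,
    sequence_class: SequenceClass = SequenceClass.T2,
    study_id: str = "unknown",
    seed: int = -1,
) -> PhantomVolume:
    img = nib.load(str(path))
    voxels = np.asarray(img.dataobj, dtype=float).transpose(2, 1, 0)
    return PhantomVolume(
        voxels=voxels, sequence_class=sequence_class, study_id=study_id, seed=seed
    )


def save_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    _check_cohort(cohort)
    cohort.to_csv(path, index=False)


def load_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"study_id": str, "patient_id": str})
    _check_cohort(df)
    df["has_t2"] = df["has_t2"].astype(bool)
    return df


def export_slices_hdf5(slices: list[ImageSlice], path: str | Path) -> None:
    """Write slices as HDF5 datasets keyed ``<study_id>/z<z_index>``."""
    with h5py.File(path, "w") as f:
        for s in slices:
            ds = f.create_dataset(f"{s.study_id}/z{s.z_index:04d}", data=s.pixels)
            ds.attrs["sequence_class"] = s.sequence_class.name


def _check_cohort(cohort: pd.DataFrame) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns {missing}")
    if cohort["study_id"].duplicated().any():
        raise ValueError("study_ids must be unique")
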