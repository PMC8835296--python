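"""Volume/mask containers, NIfTI round-tripping and the seeded cohort split.

Conventions used package-wide: voxel grids are stored axial-slice-major as
``(z, y, x)`` arrays of Hounsfield units; slice indexing is 0-based; spacing
is ``(dz, dy, dx)`` in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "CTVolume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "split_exams",
    "read_manifest",
    "write_manifest",
]


class GeometryError(ValueError):
    """Raised when an image/mask pair disagrees on shape or spacing."""


@dataclass
class CTVolume:
    """A chest CT volume in Hounsfield units.

    Parameters
    ----------
    voxels:
        ``(n_slices, rows, cols)`` array of HU values.
    spacing:
        ``(dz, dy, dx)`` voxel spacing in mm, all strictly positive.
    exam_id, participant_id, round:
        Identifiers tying the exam to a participant and screening round.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    exam_id: str = ""
    participant_id: str = ""
    round: int = 0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D (z, y, x), got ndim={self.voxels.ndim}")
        if len(self.spacing) != 3 or any(s <= 0 or not np.isfinite(s) for s in self.spacing):
            raise ValueError(f"spacing must be three strictly positive mm values, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels contain non-finite HU values")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def z_extent_mm(self) -> float:
        """Scanned cranio-caudal extent: n_slices x dz."""
        return self.n_slices * self.spacing[0]


@dataclass
class BinaryMask:
    """A {0,1} mask geometry-locked to a source image grid.

    ``reference_shape`` is the grid shape of the source (a native volume or a
    MIP stack); the mask must match it exactly.
    """

    pixels: np.ndarray
    reference_shape: tuple[int, ...] | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        vals = np.unique(self.pixels)
        if not np.isin(vals, (0, 1)).all():
            bad = vals[~np.isin(vals, (0, 1))]
            raise ValueError(f"mask contains values outside {{0,1}}: {bad.tolist()[:5]}")
        self.pixels = self.pixels.astype(np.uint8)
        if self.reference_shape is None:
            self.reference_shape = self.pixels.shape
        elif tuple(self.reference_shape) != self.pixels.shape:
            raise GeometryError(
                f"mask shape {self.pixels.shape} != reference {tuple(self.reference_shape)}"
            )

    def count(self) -> int:
        return int(self.pixels.sum())


def _affine(spacing: Sequence[float]) -> np.ndarray:
    dz, dy, dx = spacing
    return np.diag([dx, dy, dz, 1.0])


def write_volume(vol: CTVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI with spacing in the header (x, y, z data order)."""
    path = Path(path)
    img = nib.Nifti1Image(
        np.asarray(vol.voxels, dtype=np.float32).transpose(2, 1, 0), _affine(vol.spacing)
    )
    nib.save(img, path)
    return path


def read_volume(
    path: str | Path, exam_id: str = "", participant_id: str = "", round: int = 0
) -> CTVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: header carries no positive voxel spacing ({zooms})")
    data = np.asanyarray(img.dataobj).transpose(2, 1, 0)
    dx, dy, dz = (float(z) for z in zooms)
    return CTVolume(data, (dz, dy, dx), exam_id=exam_id, participant_id=participant_id, round=round)


def write_mask(mask: BinaryMask, spacing: Sequence[float], path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.pixels.transpose(2, 1, 0), _affine(spacing))
    nib.save(img, path)
    return path


def read_mask(path: str | Path) -> BinaryMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = np.asanyarray(nib.load(path).dataobj).transpose(2, 1, 0)
    return BinaryMask(np.rint(data).astype(np.int64))  # validates {0,1}


def split_exams(
    exams: Sequence[tuple[str, str]], train_fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Participant-level seeded split into disjoint train/test exam id lists.

    ``exams`` is a sequence of ``(exam_id, participant_id)`` pairs. All exams
    of one participant (e.g. both screening rounds) land on the same side, so
    no participant leaks across the split.
    """
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    participants = sorted({p for _, p in exams})
    if len(participants) < 2:
        raise ValueError(f"need >= 2 participants to split, got {len(participants)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(participants))
    n_train = int(round(train_fraction * len(participants)))
    n_train = min(max(n_train, 1), len(participants) - 1)
    train_p = {participants[i] for i in order[:n_train]}
    train = [e for e, p in exams if p in train_p]
    test = [e for e, p in exams if p not in train_p]
    return train, test


def write_manifest(rows: Sequence[dict], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(list(rows)).to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
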