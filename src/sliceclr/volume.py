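"""NIfTI volume ingestion, intensity normalization and coronal slice extraction.

A T1-weighted scan registered to MNI space has a fixed anatomical frame, so
the coronal (anterior-posterior) axis can be read off the NIfTI affine. The
pipeline decomposes each 3D volume into the 2D coronal planes of a central
window: for the standard 169 x 208 x 179 crop, the coronal extent is 208
and the central 120 planes cover the hippocampus and temporal lobe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume",
    "SliceRecord",
    "load_volume",
    "save_volume",
    "normalize_intensity",
    "select_middle_slices",
    "extract_slices",
    "prepare_slices",
    "read_manifest",
    "write_manifest",
]

MANIFEST_COLUMNS = ["scan_path", "participant_id", "diagnosis"]


@dataclass
class Volume:
    """A 3D scalar image with axis-role and spacing metadata.

    ``coronal_axis`` names the array axis running anterior-posterior;
    slicing perpendicular to it yields coronal planes.
    """

    data: np.ndarray
    coronal_axis: int
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    source_path: str = ""
    volume_id: str = ""
    participant_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("all three dimensions must be >= 1")
        if self.coronal_axis not in (0, 1, 2):
            raise ValueError("coronal_axis must be 0, 1 or 2")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if np.isnan(self.data).any():
            raise ValueError(f"NaN voxels in volume {self.source_path or self.volume_id!r}")

    @property
    def coronal_extent(self) -> int:
        return self.data.shape[self.coronal_axis]


@dataclass
class SliceRecord:
    """One coronal plane with provenance back to its source scan."""

    pixels: np.ndarray
    volume_id: str
    participant_id: str
    slice_index: int
    label: str | None = None


def _coronal_axis_from_affine(affine: np.ndarray) -> int:
    """Array axis closest to the anatomical anterior-posterior direction.

    nibabel's axis codes give, per array axis, the nearest RAS direction;
    'A'/'P' marks the coronal-normal axis.
    """
    codes = nib.orientations.aff2axcodes(affine)
    for ax, code in enumerate(codes):
        if code in ("A", "P"):
            return ax
    raise ValueError(f"could not identify an anterior-posterior axis (codes={codes})")


def load_volume(path: str | Path, coronal_axis: int | None = None,
                volume_id: str = "", participant_id: str = "",
                label: str | None = None) -> Volume:
    """Read a 3D NIfTI file into a :class:`Volume`.

    ``coronal_axis`` overrides affine-based inference (useful for
    headerless fixtures with an identity affine).
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several error types
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    if coronal_axis is None:
        coronal_axis = _coronal_axis_from_affine(img.affine)
    zooms = img.header.get_zooms()[:3]
    return Volume(
        data=np.asarray(data, dtype=np.float64),
        coronal_axis=coronal_axis,
        spacing=tuple(float(z) for z in zooms),
        source_path=str(path),
        volume_id=volume_id or path.name.split(".")[0],
        participant_id=participant_id,
        label=label,
    )


def save_volume(v: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with an affine encoding spacing and axis roles.

    The affine is diagonal with the coronal axis mapped to the anatomical
    A-P (y) direction so that :func:`load_volume` round-trips the axis role.
    """
    perm_to_ras = {0: [1, 0, 2], 1: [0, 1, 2], 2: [0, 2, 1]}[v.coronal_axis]
    affine = np.zeros((4, 4))
    for array_axis, world_axis in enumerate(perm_to_ras):
        affine[world_axis, array_axis] = v.spacing[array_axis]
    affine[3, 3] = 1.0
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def normalize_intensity(v: Volume, mode: str = "minmax") -> Volume:
    """Rescale voxel intensities; ``minmax`` to [0, 1] or ``zscore`` to (0, 1).

    A constant volume maps to all zeros under ``minmax`` and is an error
    under ``zscore``.
    """
    data = v.data
    if not np.isfinite(data).all():
        raise ValueError("volume contains non-finite values")
    if mode == "minmax":
        lo, hi = float(data.min()), float(data.max())
        out = np.zeros_like(data, dtype=np.float64) if hi == lo else (data - lo) / (hi - lo)
    elif mode == "zscore":
        sd = float(data.std())
        if sd == 0.0:
            raise ValueError("zscore normalization of a constant volume is undefined")
        out = (data - data.mean()) / sd
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return Volume(out, v.coronal_axis, v.spacing, v.source_path,
                  v.volume_id, v.participant_id, v.label)


def select_middle_slices(coronal_extent: int, n_keep: int) -> np.ndarray:
    """Indices of the ``n_keep`` consecutive central planes.

    0-based half-open window ``[start, start + n_keep)`` with
    ``start = (coronal_extent - n_keep) // 2``; when the discarded margin
    is odd the extra discarded plane falls on the high-index side.
    """
    if n_keep < 1 or n_keep > coronal_extent:
        raise ValueError(
            f"n_keep must be in [1, {coronal_extent}], got {n_keep}")
    start = (coronal_extent - n_keep) // 2
    return np.arange(start, start + n_keep)


def extract_slices(v: Volume, indices) -> list[SliceRecord]:
    """Cut the given coronal planes out of a volume, keeping provenance."""
    indices = np.asarray(indices, dtype=int)
    extent = v.coronal_extent
    if indices.size and (indices.min() < 0 or indices.max() >= extent):
        raise IndexError(f"slice index out of range [0, {extent})")
    records = []
    for idx in indices:
        pixels = np.take(v.data, int(idx), axis=v.coronal_axis)
        records.append(SliceRecord(
            pixels=np.ascontiguousarray(pixels),
            volume_id=v.volume_id,
            participant_id=v.participant_id,
            slice_index=int(idx),
            label=v.label,
        ))
    return records


def prepare_slices(v: Volume, n_keep: int) -> list[SliceRecord]:
    """Central coronal window of a volume, each plane min-max scaled to [0, 1].

    Per-slice min-max is the default intensity normalization before
    augmentation/embedding; a constant plane maps to all zeros.
    """
    records = extract_slices(v, select_middle_slices(v.coronal_extent, n_keep))
    for r in records:
        lo, hi = float(r.pixels.min()), float(r.pixels.max())
        r.pixels = (np.zeros_like(r.pixels, dtype=np.float64) if hi == lo
                    else (r.pixels - lo) / (hi - lo))
    return records


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a scan manifest TSV with columns scan_path, participant_id, diagnosis."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns {missing}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
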