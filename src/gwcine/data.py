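"""Core data model and I/O for 2D dynamic (cine) image sequences.

A cine sequence is a stack of N single-channel 2D frames acquired over one
motion cycle (e.g. one cardiac cycle in cine MRI).  Registration aligns all
frames to a common template image through per-frame dense displacement
fields.  The displacement convention used throughout the package is
*pull/backward warping on the template grid*:

    registered_n(x) = frame_n(x + u_n(x))

where ``x = (row, col)`` indexes the template grid with 0-based pixel
coordinates and ``u_n`` is stored in pixels of the preprocessed grid with
component 0 along rows (axis 1 of the frame stack) and component 1 along
columns (axis 2).  All-zero displacements therefore represent the identity
transform.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "CineSequence",
    "DeformationSequence",
    "RegionMask",
    "load_sequence",
    "save_sequence",
    "preprocess",
    "save_fields",
    "load_fields",
    "DISPLACEMENT_CONVENTION",
    "FIELD_AXIS_ORDER",
]

#: Metadata strings written next to every serialized deformation field.
DISPLACEMENT_CONVENTION = (
    "pull/backward warp: registered_n(x) = frame_n(x + u_n(x)); "
    "u in pixels; component 0 along rows, component 1 along columns"
)
FIELD_AXIS_ORDER = "frame, row, col, component"


@dataclass
class CineSequence:
    """N single-channel 2D frames over one motion cycle.

    Parameters
    ----------
    frames : ndarray, shape (N, H, W)
        Frame stack ordered by acquisition / cardiac-phase index.
    pixel_spacing : float
        Isotropic in-plane spacing in mm per pixel.
    subject_id, slice_id : str
        Opaque provenance identifiers.
    """

    frames: np.ndarray
    pixel_spacing: float = 1.0
    subject_id: str = ""
    slice_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must have shape (N, H, W); got {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("a cine sequence needs at least one frame")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def with_frames(self, frames: np.ndarray) -> "CineSequence":
        """Copy of this sequence with a new frame stack."""
        return replace(self, frames=np.asarray(frames, dtype=np.float64))

    def copy(self) -> "CineSequence":
        return replace(self, frames=self.frames.copy())


@dataclass
class DeformationSequence:
    """Per-frame dense displacement fields on the template grid.

    ``displacements`` has shape (N, H, W, 2) with pixel-unit components
    ``u1`` along rows and ``u2`` along columns (see module docstring for
    the warping convention).
    """

    displacements: np.ndarray

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=np.float64)
        if self.displacements.ndim != 4 or self.displacements.shape[-1] != 2:
            raise ValueError(
                "displacements must have shape (N, H, W, 2); "
                f"got {self.displacements.shape}"
            )

    @classmethod
    def identity(cls, n_frames: int, shape: tuple[int, int]) -> "DeformationSequence":
        """All-zero fields: the identity transform for every frame."""
        return cls(np.zeros((n_frames, *shape, 2)))

    @property
    def n_frames(self) -> int:
        return self.displacements.shape[0]

    @property
    def field_shape(self) -> tuple[int, int]:
        return self.displacements.shape[1], self.displacements.shape[2]

    def matches(self, seq: CineSequence) -> bool:
        return (
            self.n_frames == seq.n_frames and self.field_shape == seq.frame_shape
        )

    def negated(self) -> "DeformationSequence":
        return DeformationSequence(-self.displacements)


@dataclass
class RegionMask:
    """Boolean mask selecting the region of the template domain over which
    similarity, regularization and constraint terms are accumulated."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if not self.mask.any():
            raise ValueError("region mask must select at least one pixel")

    @classmethod
    def full(cls, shape: tuple[int, int]) -> "RegionMask":
        return cls(np.ones(shape, dtype=bool))

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "dicom_dir"
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".npz"):
        return "npz"
    if name.endswith((".h5", ".hdf5")):
        return "hdf5"
    raise ValueError(f"cannot infer container format from {path}")


def load_sequence(path: os.PathLike | str, format: str | None = None) -> CineSequence:
    """Load a cine sequence from NIfTI, a DICOM series directory, NPZ or HDF5.

    Frames are ordered by acquisition / cardiac-phase index (file order or
    DICOM InstanceNumber); pixel spacing is read from the header when present
    and defaults to 1.0 mm otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")
    fmt = format or _infer_format(path)

    if fmt == "npz":
        with np.load(path) as archive:
            frames = archive["frames"]
            spacing = float(archive["pixel_spacing"]) if "pixel_spacing" in archive else 1.0
            subject = str(archive["subject_id"]) if "subject_id" in archive else ""
            slc = str(archive["slice_id"]) if "slice_id" in archive else ""
        return CineSequence(frames, spacing, subject, slc)

    if fmt == "hdf5":
        import h5py

        with h5py.File(path, "r") as f:
            frames = f["frames"][()]
            spacing = float(f["frames"].attrs.get("pixel_spacing", 1.0))
            subject = str(f["frames"].attrs.get("subject_id", ""))
            slc = str(f["frames"].attrs.get("slice_id", ""))
        return CineSequence(frames, spacing, subject, slc)

    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).squeeze()
        if data.ndim != 3:
            raise ValueError(f"expected a 2D+time NIfTI; got shape {data.shape}")
        # NIfTI stores (H, W, N) with time last
        frames = np.moveaxis(data, -1, 0)
        zooms = img.header.get_zooms()
        spacing = float(zooms[0]) if len(zooms) else 1.0
        return CineSequence(frames, spacing, subject_id=path.stem)

    if fmt == "dicom_dir":
        import pydicom

        files = sorted(p for p in path.iterdir() if p.is_file())
        slices = []
        for p in files:
            try:
                ds = pydicom.dcmread(str(p))
            except Exception:
                continue
            slices.append(ds)
        if not slices:
            raise IOError(f"no readable DICOM files in {path}")
        slices.sort(key=lambda ds: int(getattr(ds, "InstanceNumber", 0)))
        arrays = [ds.pixel_array.astype(np.float64) for ds in slices]
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise ValueError(f"DICOM frames have unequal shapes: {sorted(shapes)}")
        ds0 = slices[0]
        spacing = float(ds0.PixelSpacing[0]) if hasattr(ds0, "PixelSpacing") else 1.0
        return CineSequence(
            np.stack(arrays),
            spacing,
            subject_id=str(getattr(ds0, "PatientID", "")),
            slice_id=str(getattr(ds0, "SeriesInstanceUID", "")),
        )

    raise ValueError(f"unknown format {fmt!r}")


def save_sequence(seq: CineSequence, path: os.PathLike | str) -> None:
    """Write a sequence to NPZ or HDF5 (chosen by extension)."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith(".npz"):
        np.savez(
            path,
            frames=seq.frames,
            pixel_spacing=seq.pixel_spacing,
            subject_id=seq.subject_id,
            slice_id=seq.slice_id,
        )
    elif name.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as f:
            d = f.create_dataset("frames", data=seq.frames)
            d.attrs["pixel_spacing"] = seq.pixel_spacing
            d.attrs["subject_id"] = seq.subject_id
            d.attrs["slice_id"] = seq.slice_id
    else:
        raise ValueError(f"unsupported sequence container: {path}")


def save_fields(fields: DeformationSequence, path: os.PathLike | str) -> None:
    """Write deformation fields with axis-order and convention metadata."""
    path = Path(path)
    name = path.name.lower()
    meta = json.dumps(
        {"axis_order": FIELD_AXIS_ORDER, "convention": DISPLACEMENT_CONVENTION}
    )
    if name.endswith(".npz"):
        np.savez(path, displacements=fields.displacements, metadata=meta)
    elif name.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as f:
            d = f.create_dataset("displacements", data=fields.displacements)
            d.attrs["axis_order"] = FIELD_AXIS_ORDER
            d.attrs["convention"] = DISPLACEMENT_CONVENTION
    else:
        raise ValueError(f"unsupported field container: {path}")


def load_fields(
    path: os.PathLike | str, sequence: CineSequence | None = None
) -> DeformationSequence:
    """Load deformation fields; optionally validate against a paired sequence."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    name = path.name.lower()
    if name.endswith(".npz"):
        with np.load(path) as archive:
            disp = archive["displacements"]
    elif name.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as f:
            disp = f["displacements"][()]
    else:
        raise ValueError(f"unsupported field container: {path}")
    fields = DeformationSequence(disp)
    if sequence is not None and not fields.matches(sequence):
        raise ValueError(
            f"field shape {fields.displacements.shape[:3]} does not match "
            f"sequence shape {(sequence.n_frames, *sequence.frame_shape)}"
        )
    return fields


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _center_crop_or_pad(frame: np.ndarray, size: int) -> np.ndarray:
    out = frame
    for axis in (0, 1):
        n = out.shape[axis]
        if n > size:
            start = (n - size) // 2
            out = np.take(out, np.arange(start, start + size), axis=axis)
        elif n < size:
            before = (size - n) // 2
            after = size - n - before
            pad = [(0, 0), (0, 0)]
            pad[axis] = (before, after)
            out = np.pad(out, pad, mode="constant")
    return out


def normalize_intensity(frames: np.ndarray) -> np.ndarray:
    """Sequence-level min-max normalization to [0, 1].

    The minimum and maximum are taken over the *whole* sequence so that
    relative intensity changes between frames are preserved.  A constant
    sequence maps to all zeros.
    """
    lo = frames.min()
    hi = frames.max()
    if hi <= lo:
        return np.zeros_like(frames)
    return (frames - lo) / (hi - lo)


def preprocess(
    seq: CineSequence, target_spacing_mm: float = 1.0, crop_size: int = 320
) -> CineSequence:
    """Resample to a target isotropic spacing, center-crop/pad, and normalize.

    Mirrors the standard cine preparation: bilinear resampling to
    ``target_spacing_mm``, central cropping (zero padding when smaller) to a
    square ``crop_size``, and joint min-max intensity normalization of the
    whole sequence to [0, 1].
    """
    if target_spacing_mm <= 0:
        raise ValueError("target_spacing_mm must be positive")
    if crop_size < 8:
        raise ValueError("crop_size must be at least 8")

    factor = seq.pixel_spacing / target_spacing_mm
    frames = seq.frames
    if not np.isclose(factor, 1.0):
        frames = np.stack(
            [ndimage.zoom(f, factor, order=1, mode="nearest") for f in frames]
        )
    frames = np.stack([_center_crop_or_pad(f, crop_size) for f in frames])
    frames = normalize_intensity(frames)
    return CineSequence(frames, target_spacing_mm, seq.subject_id, seq.slice_id)
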