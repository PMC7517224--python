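"""Seedable synthetic cine phantom with known ground-truth periodic motion.

The phantom emulates the statistical structure of short-axis cine cardiac MR
slices: a textured quasi-circular object, smooth elastic motion that is
periodic over one cycle, joint intensity normalization to [0, 1], and
additive Gaussian noise.  It provides the ground-truth displacement of every
frame so that registration accuracy can be measured exactly — something the
clinical data it stands in for cannot offer.

Motion model
------------
The displacement generating frame ``n`` from the phase-0 base image is

    u_n(x) = A * sin(2 pi n / N) * s(x)

with ``A`` the amplitude in pixels and ``s`` a smooth (bandlimited) spatial
profile with max |s| = 1.  For the default ``radial_contraction`` model,
``s`` points radially inward with magnitude given by a few Gaussian bumps
centered on a circular band — mimicking systolic contraction of the
myocardium.  Frames are produced by pull-warping the base image with
``u_n``; the returned ground truth is ``u_n`` itself, expressed in the same
pull-warp convention as :class:`~gwcine.data.DeformationSequence`.  A
perfect registrar pulling frame ``n`` back onto the base therefore recovers
approximately the *negated* ground truth (the first-order inverse), and the
per-pixel temporal sum of the ground truth vanishes exactly when N is even
(the sine sums to zero).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .data import CineSequence, DeformationSequence, normalize_intensity
from .warp import warp

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset", "distant_frame_pair"]


@dataclass
class PhantomSpec:
    """Parameters of one synthetic cine sequence.

    Defaults give the desk-scale study conditions used throughout the test
    battery: 64x64 frames, 10 phases, 3 px peak displacement, noise standard
    deviation 0.01 in normalized intensity units.
    """

    image_size: int = 64
    num_frames: int = 10
    motion_amplitude_px: float = 3.0
    motion_model: str = "radial_contraction"
    noise_std: float = 0.01
    texture: str = "rings"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_frames < 2:
            raise ValueError("num_frames must be >= 2")
        if self.motion_amplitude_px < 0:
            raise ValueError("motion_amplitude_px must be >= 0")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        if self.motion_model not in ("radial_contraction", "gaussian_bumps"):
            raise ValueError(f"unknown motion_model {self.motion_model!r}")
        if self.texture not in ("rings", "blobs"):
            raise ValueError(f"unknown texture {self.texture!r}")


def _base_image(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    size = spec.image_size
    rows, cols = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    center = (size - 1) / 2.0
    r = np.hypot(rows - center, cols - center)

    if spec.texture == "rings":
        # concentric rings inside a disk, ring period ~8 px, soft edge
        period = max(6.0, size / 8.0)
        rings = 0.5 + 0.5 * np.cos(2 * np.pi * r / period)
        disk = 1.0 / (1.0 + np.exp((r - 0.42 * size) / 1.5))
        base = 0.15 + 0.75 * rings * disk
    else:  # blobs
        base = np.full((size, size), 0.15)
        for _ in range(8):
            cr, cc = rng.uniform(0.15 * size, 0.85 * size, size=2)
            sigma = rng.uniform(0.04 * size, 0.12 * size)
            amp = rng.uniform(0.3, 0.8)
            base += amp * np.exp(
                -((rows - cr) ** 2 + (cols - cc) ** 2) / (2 * sigma**2)
            )
    # low-amplitude smooth background texture so no region is exactly flat
    bg = ndimage.gaussian_filter(rng.standard_normal((size, size)), 2.0)
    base = base + 0.05 * bg / max(np.abs(bg).max(), 1e-12)
    return np.clip(base, 0.0, None)


def _spatial_profile(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth profile s(x), shape (H, W, 2), max vector norm 1."""
    size = spec.image_size
    rows, cols = np.meshgrid(
        np.arange(size, dtype=float), np.arange(size, dtype=float), indexing="ij"
    )
    center = (size - 1) / 2.0
    dr = rows - center
    dc = cols - center
    r = np.hypot(dr, dc)
    n_bumps = int(rng.integers(2, 5))

    if spec.motion_model == "radial_contraction":
        ring_radius = 0.30 * size
        sigma = 0.10 * size
        angles = np.arctan2(dr, dc)
        mag = np.zeros((size, size))
        for _ in range(n_bumps):
            theta = rng.uniform(-np.pi, np.pi)
            ang_width = rng.uniform(0.6, 1.2)
            radial = np.exp(-((r - ring_radius) ** 2) / (2 * sigma**2))
            angular = np.exp(
                -(np.angle(np.exp(1j * (angles - theta))) ** 2) / (2 * ang_width**2)
            )
            mag += radial * angular
        with np.errstate(invalid="ignore", divide="ignore"):
            unit_r = np.where(r > 1e-9, dr / np.maximum(r, 1e-9), 0.0)
            unit_c = np.where(r > 1e-9, dc / np.maximum(r, 1e-9), 0.0)
        # inward-pointing: toward the center
        s = np.stack([-unit_r * mag, -unit_c * mag], axis=-1)
    else:  # gaussian_bumps: bumps with random directions
        s = np.zeros((size, size, 2))
        for _ in range(n_bumps):
            cr, cc = rng.uniform(0.2 * size, 0.8 * size, size=2)
            sigma = rng.uniform(0.08 * size, 0.15 * size)
            direction = rng.standard_normal(2)
            direction /= np.linalg.norm(direction)
            bump = np.exp(-((rows - cr) ** 2 + (cols - cc) ** 2) / (2 * sigma**2))
            s += bump[..., None] * direction

    norm = np.linalg.norm(s, axis=-1).max()
    if norm > 0:
        s = s / norm
    return s


def generate_phantom(spec: PhantomSpec) -> tuple[CineSequence, DeformationSequence]:
    """Generate one phantom sequence and its ground-truth motion.

    Returns the normalized noisy sequence and the fields ``u_n`` that warped
    the base image into each frame (pull convention, phase-0 reference).
    Deterministic for a fixed spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    base = _base_image(spec, rng)
    profile = _spatial_profile(spec, rng)
    n = spec.num_frames
    phases = np.sin(2 * np.pi * np.arange(n) / n)
    fields = (
        spec.motion_amplitude_px * phases[:, None, None, None] * profile[None]
    )
    frames = np.stack([warp(base, u) for u in fields])
    if spec.noise_std > 0:
        frames = frames + rng.normal(0.0, spec.noise_std, size=frames.shape)
    frames = normalize_intensity(frames)
    seq = CineSequence(
        frames, pixel_spacing=1.0, subject_id=f"phantom-{spec.seed}", slice_id="0"
    )
    return seq, DeformationSequence(fields)


def distant_frame_pair(spec: PhantomSpec) -> tuple[int, int]:
    """Indices of the two most 'distant' phases: peak contraction and rest.

    The analogue of the systole/diastole pair used for evaluation sampling:
    the frame of maximum displacement (|sin| maximal, n ~ N/4) and the rest
    frame (n = 0).
    """
    n = spec.num_frames
    # round before argmax: |sin| ties (e.g. n and N/2 - n) go to the lower index
    peak = int(np.argmax(np.round(np.abs(np.sin(2 * np.pi * np.arange(n) / n)), 9)))
    return peak, 0


def generate_dataset(
    n_sequences: int,
    spec_ranges: dict[str, tuple | list] | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> list[tuple[CineSequence, DeformationSequence]]:
    """Generate a reproducible list of phantoms with per-sequence specs.

    ``spec_ranges`` maps :class:`PhantomSpec` field names to either a
    ``(low, high)`` tuple (floats drawn uniformly) or a list of choices.
    Fields not listed keep the value from ``base_spec``.  Each sequence gets
    its own seed derived from ``seed``, so collapsing all ranges to points
    still yields distinct textures and noise realizations.
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    spec_ranges = {} if spec_ranges is None else spec_ranges
    for name, rng_spec in spec_ranges.items():
        if not hasattr(PhantomSpec, "__dataclass_fields__") or name not in PhantomSpec.__dataclass_fields__:
            raise ValueError(f"unknown PhantomSpec field {name!r}")
        if isinstance(rng_spec, (list, tuple)) and len(rng_spec) == 0:
            raise ValueError(f"empty range for {name!r}")
    base = base_spec or PhantomSpec()
    master = np.random.default_rng(seed)
    out = []
    for i in range(n_sequences):
        kwargs = {}
        for name, rng_spec in spec_ranges.items():
            if isinstance(rng_spec, tuple) and len(rng_spec) == 2 and all(
                isinstance(v, (int, float)) for v in rng_spec
            ):
                lo, hi = rng_spec
                val = master.uniform(lo, hi)
                if isinstance(getattr(base, name), int):
                    val = int(round(val))
                kwargs[name] = val
            else:
                kwargs[name] = rng_spec[int(master.integers(len(rng_spec)))]
        sub_seed = int(master.integers(0, 2**31 - 1))
        spec = replace(base, seed=sub_seed, **kwargs)
        out.append(generate_phantom(spec))
    return out
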