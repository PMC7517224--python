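"""Differentiable bilinear warping (spatial transformation).

Implements the pull/backward warp ``out(x) = image(x + u(x))`` with bilinear
interpolation and clamp-to-edge boundary handling, together with its exact
analytic derivatives with respect to both the image and the displacement
field.  The derivatives are what make the whole registration loss trainable
by gradient descent, so they are checked against finite differences in the
test suite.

Clamp-to-edge (rather than zero fill) is used so that out-of-range samples
replicate border intensities instead of introducing spurious dark borders
that would corrupt SSD values and template averages.
"""

from __future__ import annotations

import numpy as np

from .data import CineSequence, DeformationSequence

__all__ = ["warp", "warp_backward", "warp_sequence"]


def _sample_coords(image: np.ndarray, field: np.ndarray):
    h, w = image.shape
    rows, cols = np.meshgrid(
        np.arange(h, dtype=np.float64), np.arange(w, dtype=np.float64), indexing="ij"
    )
    r = rows + field[..., 0]
    c = cols + field[..., 1]
    # clamp-to-edge; remember where clamping saturated the coordinate so the
    # derivative w.r.t. the field vanishes there (subgradient of clip)
    r_in = (r > 0.0) & (r < h - 1)
    c_in = (c > 0.0) & (c < w - 1)
    r = np.clip(r, 0.0, h - 1)
    c = np.clip(c, 0.0, w - 1)
    r0 = np.floor(r).astype(np.intp)
    c0 = np.floor(c).astype(np.intp)
    r0 = np.minimum(r0, h - 2) if h > 1 else r0
    c0 = np.minimum(c0, w - 2) if w > 1 else c0
    r1 = np.minimum(r0 + 1, h - 1)
    c1 = np.minimum(c0 + 1, w - 1)
    fr = r - r0
    fc = c - c0
    return r0, r1, c0, c1, fr, fc, r_in, c_in


def warp(image: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Bilinearly sample ``image`` at ``x + u(x)``.

    Parameters
    ----------
    image : ndarray, shape (H, W)
    field : ndarray, shape (H, W, 2)
        Displacement in pixels; component 0 along rows, 1 along columns.
    """
    image = np.asarray(image, dtype=np.float64)
    field = np.asarray(field, dtype=np.float64)
    if field.shape[:2] != image.shape or field.shape[-1] != 2:
        raise ValueError(
            f"field shape {field.shape} incompatible with image {image.shape}"
        )
    r0, r1, c0, c1, fr, fc, _, _ = _sample_coords(image, field)
    top = image[r0, c0] * (1 - fc) + image[r0, c1] * fc
    bot = image[r1, c0] * (1 - fc) + image[r1, c1] * fc
    return top * (1 - fr) + bot * fr


def warp_backward(
    image: np.ndarray, field: np.ndarray, grad_output: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Backpropagate ``grad_output`` through :func:`warp`.

    Returns ``(grad_image, grad_field)``: the adjoint of the interpolation
    (a scatter-add of the bilinear weights) and the chain-rule product of
    ``grad_output`` with the spatial derivative of the interpolant.  Where
    the clamped sample coordinate saturated, the field derivative is zero.
    """
    image = np.asarray(image, dtype=np.float64)
    field = np.asarray(field, dtype=np.float64)
    grad_output = np.asarray(grad_output, dtype=np.float64)
    r0, r1, c0, c1, fr, fc, r_in, c_in = _sample_coords(image, field)

    w00 = (1 - fr) * (1 - fc)
    w01 = (1 - fr) * fc
    w10 = fr * (1 - fc)
    w11 = fr * fc

    grad_image = np.zeros_like(image)
    np.add.at(grad_image, (r0, c0), grad_output * w00)
    np.add.at(grad_image, (r0, c1), grad_output * w01)
    np.add.at(grad_image, (r1, c0), grad_output * w10)
    np.add.at(grad_image, (r1, c1), grad_output * w11)

    # d out / d u1: difference along rows, interpolated along cols
    d_dr = (image[r1, c0] - image[r0, c0]) * (1 - fc) + (
        image[r1, c1] - image[r0, c1]
    ) * fc
    d_dc = (image[r0, c1] - image[r0, c0]) * (1 - fr) + (
        image[r1, c1] - image[r1, c0]
    ) * fr
    grad_field = np.empty_like(field)
    grad_field[..., 0] = grad_output * d_dr * r_in
    grad_field[..., 1] = grad_output * d_dc * c_in
    return grad_image, grad_field


def warp_sequence(seq: CineSequence, fields: DeformationSequence) -> CineSequence:
    """Frame-wise warp: the registered sequence on the template grid."""
    if not fields.matches(seq):
        raise ValueError(
            f"fields {fields.displacements.shape[:3]} do not match sequence "
            f"{(seq.n_frames, *seq.frame_shape)}"
        )
    registered = np.stack(
        [warp(f, u) for f, u in zip(seq.frames, fields.displacements)]
    )
    return seq.with_frames(registered)
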