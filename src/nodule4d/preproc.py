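"""Preprocessing operators: median filter, local contrast, drift registration,
and the two temporal operators that underlie bleb extraction.

All operators take and return plain (T, Z, Y, X) single-channel arrays or a
full :class:`~nodule4d.stackio.ImageStack`; stack-level wrappers apply the
operator per timepoint, per channel.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure
from skimage.registration import phase_cross_correlation

from .stackio import ImageStack

log = logging.getLogger(__name__)


def _per_tc(stack: ImageStack, fn, dtype=None) -> ImageStack:
    out = np.empty_like(stack.data, dtype=dtype or stack.data.dtype)
    for t in range(stack.data.shape[0]):
        for c in range(stack.data.shape[2]):
            out[t, :, c] = fn(stack.data[t, :, c])
    return stack.with_data(out)


def median_filter(stack: ImageStack, radius: int = 1, three_d: bool = False) -> ImageStack:
    """Median filter applied per timepoint, per channel.

    By default the kernel is in-plane (2D per Z slice) because voxels are
    typically anisotropic; ``three_d=True`` uses a cubic kernel.
    Edges are handled by reflection.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1 voxel")
    size = 2 * radius + 1
    zyx = stack.data.shape[1], stack.data.shape[3], stack.data.shape[4]
    kernel = (size, size, size) if three_d else (1, size, size)
    for k, n in zip(kernel, zyx):
        if k > n:
            raise ValueError(f"median kernel {kernel} exceeds volume shape {zyx}")
    out = _per_tc(stack, lambda v: ndi.median_filter(v, size=kernel, mode="reflect"))
    log.info("median_filter radius=%d three_d=%s on shape %s", radius, three_d, stack.shape)
    return out


def local_contrast(
    stack: ImageStack, block_size: int = 32, clip: float = 0.01
) -> ImageStack:
    """Block-local adaptive histogram equalisation (CLAHE contract).

    Intensities are rescaled per local neighbourhood; output lies in [0, 1].
    Applied in-plane per Z slice.  A constant image maps to a constant.
    """
    if block_size < 8:
        raise ValueError("block size must be >= 8 voxels in-plane")

    def _one(vol: np.ndarray) -> np.ndarray:
        lo, hi = float(vol.min()), float(vol.max())
        if hi <= lo:  # constant volume: equalisation is undefined, pass through
            return np.zeros_like(vol, dtype=np.float64)
        norm = (vol - lo) / (hi - lo)
        out = np.empty_like(norm, dtype=np.float64)
        for z in range(norm.shape[0]):
            out[z] = exposure.equalize_adapthist(
                norm[z], kernel_size=block_size, clip_limit=clip
            )
        return out

    out = _per_tc(stack, _one, dtype=np.float32)
    log.info("local_contrast block=%d clip=%g on shape %s", block_size, clip, stack.shape)
    return out


def temporal_min_subtract(movie: np.ndarray) -> np.ndarray:
    """Subtract the per-pixel minimum over time: ``out[t] = in[t] - min_t in``.

    Static content is suppressed to ~0; transient content is retained.
    ``movie`` has time on axis 0.
    """
    movie = np.asarray(movie, dtype=np.float64)
    if movie.shape[0] < 2:
        raise ValueError("temporal_min_subtract needs T >= 2")
    return movie - movie.min(axis=0, keepdims=True)


def frame_difference(movie: np.ndarray) -> np.ndarray:
    """Forward frame-by-frame difference, clipped at 0.

    ``out[t] = max(in[t+1] - in[t], 0)`` for t = 0..T-2; appearing structures
    are highlighted, output has T-1 frames.
    """
    movie = np.asarray(movie, dtype=np.float64)
    if movie.shape[0] < 2:
        raise ValueError("frame_difference needs T >= 2")
    return np.clip(np.diff(movie, axis=0), 0, None)


def register_drift(
    stack: ImageStack,
    mode: str = "cross-correlation",
    manual_offsets: np.ndarray | None = None,
    reference_channel: int = 0,
) -> tuple[ImageStack, np.ndarray]:
    """Correct XYZ translation drift over a time series.

    ``mode='manual'`` applies the supplied integer (z, y, x) offset per
    timepoint.  ``mode='cross-correlation'`` estimates, per timepoint, the
    integer translation maximising correlation with the first timepoint and
    applies its inverse.  Returns the corrected stack and the (T, 3) applied
    offsets.
    """
    if mode not in ("manual", "cross-correlation"):
        raise ValueError(f"unknown registration mode {mode!r}")
    T = stack.data.shape[0]
    if mode == "manual":
        if manual_offsets is None:
            raise ValueError("manual mode requires manual_offsets")
        offsets = np.asarray(manual_offsets, dtype=int)
        if offsets.shape != (T, 3):
            raise ValueError(f"manual_offsets must have shape ({T}, 3)")
    else:
        ref = stack.data[0, :, reference_channel]
        offsets = np.zeros((T, 3), dtype=int)
        for t in range(1, T):
            shift, _, _ = phase_cross_correlation(
                ref, stack.data[t, :, reference_channel], upsample_factor=1
            )
            offsets[t] = np.round(shift).astype(int)
    out = np.empty_like(stack.data)
    for t in range(T):
        dz, dy, dx = (int(v) for v in offsets[t])
        for c in range(stack.data.shape[2]):
            out[t, :, c] = np.roll(stack.data[t, :, c], (dz, dy, dx), axis=(0, 1, 2))
    log.info("register_drift mode=%s offsets=%s", mode, offsets.tolist())
    return stack.with_data(out), offsets
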