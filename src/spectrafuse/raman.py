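"""Raman-specific preprocessing: axis interpolation, cosmic-spike removal
and per-spectrum normalization.

Spike detection scores every cell of the pixels x channels matrix with a
discrete 5-point Laplacian (pixels in raster scan order, row-major by y then
x).  Cosmic spikes are single-pixel, single-to-few-channel events and light
up the Laplacian; genuine Raman bands appear at the same channel in
neighbouring pixels, so after removing the per-channel median of the score
their residual is ~0.  The residual is standardized by the map-wide robust
scale (1.4826 x MAD) and thresholded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ValidationError
from .io import SpectralMap

__all__ = [
    "SpikeMask",
    "interpolate_axis",
    "detect_spikes",
    "remove_spikes",
    "normalize",
    "scan_order",
]

NORM_METHODS = ("l2", "l1", "total_intensity")


@dataclass
class SpikeMask:
    flags: np.ndarray  # boolean, n_pixels x n_channels
    score: np.ndarray  # standardized Laplacian, same shape

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        self.score = np.asarray(self.score, dtype=float)
        if self.flags.shape != self.score.shape:
            raise ValidationError("flags and score shapes differ")

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


def interpolate_axis(m: SpectralMap, target_axis: np.ndarray) -> SpectralMap:
    """Linear per-pixel interpolation onto a new wavenumber axis.

    Extrapolation is refused: the target axis must lie within the source
    axis range.
    """
    target_axis = np.asarray(target_axis, dtype=float)
    if target_axis.ndim != 1 or np.any(np.diff(target_axis) <= 0):
        raise ParameterError("target_axis must be 1-D and strictly increasing")
    if target_axis[0] < m.axis[0] or target_axis[-1] > m.axis[-1]:
        raise ParameterError(
            "extrapolation requested: target axis "
            f"[{target_axis[0]:g}, {target_axis[-1]:g}] exceeds source "
            f"[{m.axis[0]:g}, {m.axis[-1]:g}]"
        )
    out = np.empty((m.n_pixels, target_axis.size))
    for i in range(m.n_pixels):
        out[i] = np.interp(target_axis, m.axis, m.intensities[i])
    meta = dict(m.meta)
    meta["interpolated"] = True
    return SpectralMap(out, target_axis, m.coords.copy(), m.modality, meta)


def scan_order(coords: np.ndarray) -> np.ndarray:
    """Raster (row-major by y, then x) ordering of pixel indices."""
    return np.lexsort((coords[:, 0], coords[:, 1]))


def detect_spikes(m: SpectralMap, z_threshold: float = 8.0) -> SpikeMask:
    if z_threshold <= 0:
        raise ParameterError("z_threshold must be positive")
    if m.n_pixels < 3:
        raise ParameterError(
            "single-pixel or two-pixel map: use a 1-D second difference along "
            "channels instead of the map Laplacian"
        )
    if m.n_channels < 3:
        raise ParameterError("need at least 3 channels")

    order = scan_order(m.coords)
    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    x = m.intensities[order]

    # 5-point Laplacian with edge-clamped neighbours.
    up = np.vstack([x[:1], x[:-1]])
    down = np.vstack([x[1:], x[-1:]])
    left = np.hstack([x[:, :1], x[:, :-1]])
    right = np.hstack([x[:, 1:], x[:, -1:]])
    lap = up + down + left + right - 4.0 * x

    # Shared spectral structure (true bands) is constant down a channel
    # column of the Laplacian; remove it before standardizing.
    resid = lap - np.median(lap, axis=0, keepdims=True)
    mad = np.median(np.abs(resid - np.median(resid)))
    scale = 1.4826 * mad
    if scale <= 0:
        scale = np.finfo(float).tiny
    z = resid / scale
    flags = np.abs(z) > z_threshold
    return SpikeMask(flags[inv], z[inv])


def remove_spikes(m: SpectralMap, mask: SpikeMask) -> SpectralMap:
    """Replace flagged cells by linear interpolation along the channel axis.

    Runs of adjacent flagged channels are filled as one gap; flags at the
    spectrum edges take the nearest unflagged value (constant extension).
    All unflagged cells are returned bit-identical.
    """
    if mask.flags.shape != m.intensities.shape:
        raise ValidationError("mask shape does not match map")
    out = m.intensities.copy()
    ch = np.arange(m.n_channels)
    for i in np.flatnonzero(mask.flags.any(axis=1)):
        good = ~mask.flags[i]
        if not good.any():
            raise ValidationError(f"spectrum unrecoverable: pixel {i} fully flagged")
        out[i, ~good] = np.interp(ch[~good], ch[good], out[i, good])
    n_replaced = int(mask.flags.sum())
    return m.with_intensities(out, spikes_removed=n_replaced)


def normalize(m: SpectralMap, method: str = "l2") -> SpectralMap:
    """Per-spectrum normalization.

    ``l2`` divides by sqrt(sum y^2), ``l1`` by sum |y|, ``total_intensity``
    by the signed sum.  The latter two differ only when negative values are
    present (e.g. after baseline subtraction).
    """
    if method not in NORM_METHODS:
        raise ParameterError(f"method must be one of {NORM_METHODS}")
    y = m.intensities
    if method == "l2":
        norms = np.sqrt(np.sum(y * y, axis=1))
    elif method == "l1":
        norms = np.sum(np.abs(y), axis=1)
    else:
        norms = np.sum(y, axis=1)
        bad = np.flatnonzero(norms <= 0)
        if bad.size:
            raise ValidationError(
                f"total_intensity normalization: non-positive sum at pixel {bad[0]}"
            )
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValidationError(f"zero norm at pixel {bad[0]}")
    return m.with_intensities(y / norms[:, None], normalized=method)
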