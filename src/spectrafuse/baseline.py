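"""SNIP background estimation shared by the Raman and MALDI pipelines.

The estimator iterates a clipping window over each spectrum: at window
half-width ``p`` every sample is replaced by ``min(y_i, (y_{i-p} + y_{i+p})/2)``
with out-of-range neighbour indices clamped to the spectrum edges.  After
``max_window`` passes the clipped signal is the baseline estimate.  An
optional log-log-sqrt (LLS) compression is applied before clipping and
inverted afterwards; it compresses dynamic range, which suits
shot-noise-dominated mass-spectral backgrounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .io import SpectralMap

__all__ = ["SnipParams", "snip_baseline", "subtract_baseline"]

_ORDERS = ("increasing", "decreasing")


@dataclass(frozen=True)
class SnipParams:
    max_window: int = 40
    lls: bool = False
    order: str = "increasing"
    smooth_half_width: int = 0   # moving-average pre-smoothing (0 = off)

    def __post_init__(self) -> None:
        if self.max_window < 1:
            raise ParameterError("max_window must be >= 1")
        if self.order not in _ORDERS:
            raise ParameterError(f"order must be one of {_ORDERS}")
        if self.smooth_half_width < 0:
            raise ParameterError("smooth_half_width must be >= 0")

    def validate_length(self, n_channels: int) -> None:
        if self.max_window >= n_channels / 2:
            raise ParameterError(
                f"max_window {self.max_window} too large for {n_channels} channels "
                "(must be < n_channels / 2)"
            )


def _lls(y: np.ndarray) -> np.ndarray:
    return np.log(np.log(np.sqrt(y + 1.0) + 1.0) + 1.0)


def _lls_inv(v: np.ndarray) -> np.ndarray:
    return np.square(np.exp(np.exp(v) - 1.0) - 1.0) - 1.0


def snip_baseline(y: np.ndarray, params: SnipParams) -> np.ndarray:
    """Estimate the baseline of one spectrum (1-D) or a stack of them (2-D).

    The clipping operates along the last axis.  Without LLS or pre-smoothing
    the returned baseline is pointwise <= y; with smoothing the baseline runs
    through the middle of the noise, so the corrected spectrum has negative
    values near noise (which downstream normalization must preserve).
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[-1]
    params.validate_length(n)
    if n <= 2 * params.max_window:
        raise ParameterError("spectrum too short for the requested window")

    if params.smooth_half_width > 0:
        from scipy.ndimage import uniform_filter1d

        y = uniform_filter1d(y, 2 * params.smooth_half_width + 1,
                             axis=-1, mode="nearest")

    # LLS needs non-negative input; shift by the minimum and undo afterwards.
    offset = 0.0
    work = y
    if params.lls:
        lo = float(work.min())
        if lo < 0:
            offset = lo
            work = work - offset
        work = _lls(work)
    else:
        work = work.copy()

    windows = range(1, params.max_window + 1)
    if params.order == "decreasing":
        windows = range(params.max_window, 0, -1)
    for p in windows:
        # clip interior samples only (classic SNIP); the first/last p samples
        # keep their values, so linear ramps are exact fixed points
        mid = 0.5 * (work[..., : n - 2 * p] + work[..., 2 * p:])
        np.minimum(work[..., p: n - p], mid, out=work[..., p: n - p])

    if params.lls:
        work = _lls_inv(work) + offset
    return work


def subtract_baseline(m: SpectralMap, params: SnipParams) -> SpectralMap:
    """Per-pixel SNIP baseline subtraction; records parameters in ``meta``.

    Corrected spectra may contain negative values near noise; they are
    preserved (the distinction between the l1-norm and the signed total
    intensity depends on them).
    """
    baseline = snip_baseline(m.intensities, params)
    return m.with_intensities(
        m.intensities - baseline,
        snip={"max_window": params.max_window, "lls": params.lls,
              "order": params.order,
              "smooth_half_width": params.smooth_half_width},
    )
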