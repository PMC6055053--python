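"""MALDI-specific preprocessing: noise estimation, peak picking, phase
correction along the m/z axis, mass-relative binning and TIC normalization.

Profile spectra are never interpolated onto a common m/z grid (that would
corrupt the sharp peaks); instead peak positions are aligned (phase
correction), picked, and then merged into shared bins whose width grows
proportionally with mass (ppm tolerance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import ParameterError, ValidationError
from .io import PeakList, SpectralMap

__all__ = [
    "BinTable",
    "PhaseModel",
    "estimate_noise",
    "pick_peaks",
    "phase_correct",
    "bin_peaks",
    "tic_normalize",
    "normalize_ms",
]

MS_NORM_METHODS = ("tic", "rms", "median", "sqrt", "log", "noise")


@dataclass
class BinTable:
    """Bins produced by greedy m/z clustering.

    ``members[j]`` lists the (pixel_id, original m/z, intensity) triples
    merged into bin ``j``; every member lies within ``tolerance_ppm`` of the
    running intensity-weighted centroid at the time it was merged.
    """

    centroids: np.ndarray
    members: list
    tolerance_ppm: float

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.size and np.any(np.diff(self.centroids) <= 0):
            raise ValidationError("bin centroids must be strictly increasing")
        if len(self.members) != self.centroids.size:
            raise ValidationError("members list does not match centroids")

    @property
    def n_bins(self) -> int:
        return self.centroids.size


@dataclass
class PhaseModel:
    """Per-pixel m/z correction: corrected_mz = mz + offset (+ slope * mz)."""

    offsets: np.ndarray
    anchors: np.ndarray
    slopes: np.ndarray | None = None
    n_matched: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    unmatched: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))


def estimate_noise(y: np.ndarray) -> float:
    """Robust noise scale: 1.4826 * MAD of the first difference / sqrt(2).

    The first difference cancels smooth signal; dividing by sqrt(2) undoes
    the variance doubling of differencing.  Returns 0 (with a warning) for a
    constant spectrum.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 8:
        raise ParameterError("estimate_noise needs a 1-D spectrum of length >= 8")
    d = np.diff(y)
    mad = np.median(np.abs(d - np.median(d)))
    if mad == 0:
        if not np.any(y != y[0]):
            warnings.warn("constant spectrum: noise estimate is 0", stacklevel=2)
        return 0.0
    return float(1.4826 * mad / np.sqrt(2.0))


def pick_peaks(axis: np.ndarray, intensities: np.ndarray, snr: float = 3.0,
               pixel_id: int = 0) -> PeakList:
    """Local maxima whose height exceeds ``snr`` times the robust noise."""
    if snr <= 0:
        raise ParameterError("snr must be positive")
    axis = np.asarray(axis, dtype=float)
    y = np.asarray(intensities, dtype=float)
    noise = estimate_noise(y) if y.size >= 8 else 0.0
    idx, _ = find_peaks(y, height=snr * noise if noise > 0 else 0.0)
    idx = idx[y[idx] > 0]
    return PeakList(axis[idx], y[idx], pixel_id=pixel_id)


# ---------------------------------------------------------------------------
# phase correction
# ---------------------------------------------------------------------------

def _detect_anchors(m: SpectralMap, anchor_quantile: float, max_shift: float,
                    min_presence: float = 0.5) -> np.ndarray:
    """Stable intense peaks: local maxima of the pixel-mean spectrum above
    the given intensity quantile, present (within max_shift) in at least
    ``min_presence`` of the pixels."""
    mean = m.intensities.mean(axis=0)
    idx, _ = find_peaks(mean)
    if idx.size == 0:
        return np.array([])
    thr = np.quantile(mean, anchor_quantile)
    idx = idx[mean[idx] >= thr]
    candidates = m.axis[idx]
    if candidates.size == 0:
        return candidates
    keep = []
    for mz in candidates:
        present = 0
        for i in range(m.n_pixels):
            obs = _strongest_local_max(m.axis, m.intensities[i], mz, max_shift)
            if obs is not None:
                present += 1
        if present >= min_presence * m.n_pixels:
            keep.append(mz)
    return np.asarray(keep)


def _strongest_local_max(axis, y, mz, max_shift):
    """Tallest local maximum within +-max_shift of mz (None if none)."""
    lo = np.searchsorted(axis, mz - max_shift)
    hi = np.searchsorted(axis, mz + max_shift)
    if hi - lo < 3:
        return None
    seg = y[lo:hi]
    idx, _ = find_peaks(seg)
    if idx.size == 0:
        return None
    best = idx[np.argmax(seg[idx])]
    return float(axis[lo + best])


def _fit_shift(observed: np.ndarray, anchors: np.ndarray, linear: bool):
    """Least-squares correction so that observed + correction ~= anchors."""
    delta = observed - anchors  # the drift
    if linear and observed.size >= 2:
        c1, c0 = np.polyfit(observed, delta, 1)
        return -c0, -c1
    return -float(np.mean(delta)), 0.0


def phase_correct(data, max_shift: float = 0.5, anchor_quantile: float = 0.99,
                  anchors: np.ndarray | None = None, model: str = "offset"):
    """Align per-pixel m/z axes to a set of stable intense reference peaks.

    Parameters
    ----------
    data : SpectralMap (profile spectra) or list of PeakList
    max_shift : largest admissible |offset| in Da; anchor matches are sought
        within this window
    anchor_quantile : intensity quantile of the pixel-mean spectrum used to
        select anchors when none are given (SpectralMap input only)
    anchors : explicit anchor m/z values; required for PeakList input
    model : "offset" (default) or "linear" (offset + slope * m/z)

    Returns
    -------
    (corrected data of the same kind, PhaseModel)
    """
    if model not in ("offset", "linear"):
        raise ParameterError("model must be 'offset' or 'linear'")
    if max_shift <= 0:
        raise ParameterError("max_shift must be positive")
    linear = model == "linear"

    if isinstance(data, SpectralMap):
        if anchors is None:
            anchors = _detect_anchors(data, anchor_quantile, max_shift)
        anchors = np.asarray(anchors, dtype=float)
        if anchors.size < 2:
            raise ValidationError("no stable intense peaks found for phase correction")
        n = data.n_pixels
        offsets = np.zeros(n)
        slopes = np.zeros(n) if linear else None
        n_matched = np.zeros(n, dtype=int)
        corrected = np.empty_like(data.intensities)
        for i in range(n):
            obs, ref = [], []
            for mz in anchors:
                o = _strongest_local_max(data.axis, data.intensities[i], mz, max_shift)
                if o is not None:
                    obs.append(o)
                    ref.append(mz)
            n_matched[i] = len(obs)
            if len(obs) >= 1:
                c0, c1 = _fit_shift(np.array(obs), np.array(ref), linear)
                c0 = float(np.clip(c0, -max_shift, max_shift))
                offsets[i] = c0
                if linear:
                    slopes[i] = c1
            # corrected value at axis a = observed value at the position that
            # maps to a under the correction: a - offset (offset model)
            src = (data.axis - offsets[i]) / (1.0 + (slopes[i] if linear else 0.0))
            corrected[i] = np.interp(src, data.axis, data.intensities[i])
        out = data.with_intensities(corrected, phase_corrected=True)
        return out, PhaseModel(offsets, anchors, slopes, n_matched, n_matched == 0)

    # list of PeakList
    lists = list(data)
    if anchors is None:
        raise ParameterError("PeakList input requires explicit anchors")
    anchors = np.asarray(anchors, dtype=float)
    if anchors.size < 1:
        raise ValidationError("no stable intense peaks found for phase correction")
    n = len(lists)
    offsets = np.zeros(n)
    slopes = np.zeros(n) if linear else None
    n_matched = np.zeros(n, dtype=int)
    corrected_lists = []
    for i, pl in enumerate(lists):
        obs, ref = [], []
        for mz in anchors:
            if len(pl) == 0:
                break
            j = int(np.argmin(np.abs(pl.mz - mz)))
            if abs(pl.mz[j] - mz) <= max_shift:
                obs.append(float(pl.mz[j]))
                ref.append(mz)
        n_matched[i] = len(obs)
        if len(obs) >= 1:
            c0, c1 = _fit_shift(np.array(obs), np.array(ref), linear)
            offsets[i] = float(np.clip(c0, -max_shift, max_shift))
            if linear:
                slopes[i] = c1
        new_mz = pl.mz + offsets[i]
        if linear:
            new_mz = new_mz + slopes[i] * pl.mz
        order = np.argsort(new_mz, kind="stable")
        corrected_lists.append(PeakList(new_mz[order], pl.intensity[order], pl.pixel_id))
    return corrected_lists, PhaseModel(offsets, anchors, slopes, n_matched, n_matched == 0)


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_peaks(peak_lists, tolerance_ppm: float = 200.0,
              coords: np.ndarray | None = None):
    """Merge peak positions across pixels into shared mass-relative bins.

    All peaks are pooled and sorted by m/z; a greedy single pass opens a new
    bin whenever the next m/z exceeds the running intensity-weighted centroid
    by more than ``tolerance_ppm`` (relative, so bins widen with mass, which
    matches the mass-dependent peak width).  Returns a SpectralMap whose axis
    is the bin centroids plus the full BinTable.
    """
    if tolerance_ppm <= 0:
        raise ParameterError("tolerance_ppm must be positive")
    lists = list(peak_lists)
    if not lists or all(len(pl) == 0 for pl in lists):
        raise ValidationError("bin_peaks needs at least one nonempty PeakList")
    n_pixels = max(pl.pixel_id for pl in lists) + 1

    mz = np.concatenate([pl.mz for pl in lists])
    inten = np.concatenate([pl.intensity for pl in lists])
    pix = np.concatenate([np.full(len(pl), pl.pixel_id) for pl in lists])
    order = np.lexsort((pix, mz))  # deterministic under pixel permutation
    mz, inten, pix = mz[order], inten[order], pix[order]

    tol = tolerance_ppm * 1e-6
    centroids: list[float] = []
    members: list[list] = []
    bin_of = np.empty(mz.size, dtype=int)
    csum = wsum = 0.0
    for i in range(mz.size):
        if centroids and mz[i] - centroids[-1] <= tol * centroids[-1]:
            members[-1].append((int(pix[i]), float(mz[i]), float(inten[i])))
            w = max(float(inten[i]), 0.0)
            csum += w * mz[i]
            wsum += w
            if wsum > 0:
                centroids[-1] = csum / wsum
        else:
            centroids.append(float(mz[i]))
            members.append([(int(pix[i]), float(mz[i]), float(inten[i]))])
            w = max(float(inten[i]), 0.0)
            csum = w * mz[i]
            wsum = w
            if wsum > 0:
                centroids[-1] = csum / wsum
        bin_of[i] = len(centroids) - 1

    table = BinTable(np.array(centroids), members, tolerance_ppm)
    matrix = np.zeros((n_pixels, table.n_bins))
    np.add.at(matrix, (pix.astype(int), bin_of), inten)
    if coords is None:
        coords = np.column_stack([np.arange(n_pixels, dtype=float),
                                  np.zeros(n_pixels)])
    smap = SpectralMap(matrix, table.centroids, coords, "maldi",
                       {"binned": {"tolerance_ppm": tolerance_ppm}})
    return smap, table


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def tic_normalize(m: SpectralMap, on_zero: str = "error") -> SpectralMap:
    """Divide each spectrum by its total ion count.

    For non-negative spectra this is identical to l1 normalization.  A pixel
    with non-positive TIC raises by default; ``on_zero="drop"`` removes it.
    """
    tic = m.intensities.sum(axis=1)
    bad = np.flatnonzero(tic <= 0)
    if bad.size:
        if on_zero == "drop":
            keep = tic > 0
            m = m.select_pixels(keep)
            tic = tic[keep]
        else:
            raise ValidationError(f"zero or negative TIC at pixel {bad[0]}")
    return m.with_intensities(m.intensities / tic[:, None], normalized="tic")


def normalize_ms(m: SpectralMap, method: str = "tic") -> SpectralMap:
    """MS normalization variants sharing the tic_normalize contract shape.

    ``tic`` (default, used downstream), ``rms`` (vector norm), ``median``,
    ``sqrt`` and ``log`` (variance-stabilizing transforms), and ``noise``
    (division by the per-spectrum robust noise level).
    """
    if method not in MS_NORM_METHODS:
        raise ParameterError(f"method must be one of {MS_NORM_METHODS}")
    y = m.intensities
    if method == "tic":
        return tic_normalize(m)
    if method == "sqrt":
        if np.any(y < 0):
            raise ValidationError("sqrt normalization needs non-negative intensities")
        return m.with_intensities(np.sqrt(y), normalized="sqrt")
    if method == "log":
        if np.any(y < 0):
            raise ValidationError("log normalization needs non-negative intensities")
        return m.with_intensities(np.log1p(y), normalized="log")
    if method == "rms":
        norms = np.sqrt(np.mean(y * y, axis=1))
    elif method == "median":
        norms = np.median(np.where(y > 0, y, np.nan), axis=1)
        norms = np.nan_to_num(norms, nan=0.0)
    else:  # noise
        norms = np.array([estimate_noise(row) for row in y])
    bad = np.flatnonzero(~(norms > 0))
    if bad.size:
        raise ValidationError(f"non-positive {method} norm at pixel {bad[0]}")
    return m.with_intensities(y / norms[:, None], normalized=method)
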