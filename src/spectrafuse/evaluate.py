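"""Joint analysis: PCA, the cumulative-variance weighting criterion, the
weighting-coefficient sweep, loading decomposition by block, RGB score
composites and cross-modality correlation.

The quality of a block weighting is judged by how slowly the cumulative
proportion of explained variance rises with the number of principal
components: a slower rise means the variance is spread over more independent
features.  The sweep evaluates this curve over a grid of weighting
coefficients and records, for each PC count, the coefficient minimizing the
cumulative proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ValidationError
from .fuse import FusedMatrix
from .io import SpectralMap

__all__ = [
    "PCAModel",
    "SweepResult",
    "pca",
    "cumulative_curve",
    "weight_sweep",
    "split_loadings",
    "rgb_composite",
    "cross_correlation",
]


@dataclass
class PCAModel:
    mean: np.ndarray          # p
    loadings: np.ndarray      # p x k, orthonormal columns
    scores: np.ndarray        # n x k
    explained: np.ndarray     # k, variance proportions
    cumulative: np.ndarray    # k, running sum of explained
    total_variance: float     # sum of squares of centered matrix / (n - 1)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class SweepResult:
    coefficients: np.ndarray   # c values
    curves: np.ndarray         # len(coefficients) x k cumulative proportions
    argmin_per_k: np.ndarray   # coefficient minimizing cumulative, per PC count

    def curve_for(self, c: float) -> np.ndarray:
        idx = np.flatnonzero(np.isclose(self.coefficients, c))
        if idx.size == 0:
            raise ParameterError(f"coefficient {c} not in sweep grid")
        return self.curves[idx[0]]


def pca(matrix: np.ndarray, k: int) -> PCAModel:
    """Mean-centered PCA via SVD; no per-column variance scaling.

    Scaling columns to unit variance would equalize the blocks and nullify
    any block weighting, so only the column means are removed.  Explained
    proportions are taken against the total variance of the full centered
    matrix, so they remain correct under truncation (k < rank).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ParameterError("matrix must be 2-D")
    n, p = x.shape
    if n < 2:
        raise ParameterError("need at least 2 rows")
    if not 1 <= k <= min(n - 1, p):
        raise ParameterError(f"k={k} out of range [1, {min(n - 1, p)}]")
    mean = x.mean(axis=0)
    xc = x - mean
    total = float(np.sum(xc * xc)) / (n - 1)
    if total == 0:
        raise ValidationError("zero variance: matrix is constant")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # deterministic sign: largest-|.| element of each loading is positive
    loadings = vt[:k].T
    scores = u[:, :k] * s[:k]
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]
    explained = (s[:k] ** 2 / (n - 1)) / total
    return PCAModel(mean, loadings, scores, explained,
                    np.cumsum(explained), total)


def cumulative_curve(model: PCAModel, k: int | None = None) -> np.ndarray:
    if k is None:
        k = model.n_components
    if k > model.n_components:
        raise ParameterError(f"k={k} exceeds fitted components {model.n_components}")
    return model.cumulative[:k].copy()


def weight_sweep(a: SpectralMap, b: SpectralMap,
                 coefficients=None, k: int = 20) -> SweepResult:
    """PCA of ``[A | c B]`` for each weighting coefficient c.

    The default grid is 1, 2, ..., 20.  ``argmin_per_k[j]`` is the
    coefficient whose cumulative proportion at j+1 PCs is lowest (the
    optimal unmixing for that number of PCs).
    """
    if coefficients is None:
        coefficients = np.arange(1, 21, dtype=float)
    coefficients = np.asarray(coefficients, dtype=float)
    if np.any(coefficients <= 0):
        raise ParameterError("coefficients must be positive")
    if a.n_pixels != b.n_pixels or not np.allclose(a.coords, b.coords):
        raise ValidationError("blocks are not pixel-aligned")
    k = min(k, a.n_pixels - 1, a.n_channels + b.n_channels)
    curves = np.empty((coefficients.size, k))
    for i, c in enumerate(coefficients):
        fused = np.hstack([a.intensities, c * b.intensities])
        curves[i] = pca(fused, k).cumulative
    argmin = coefficients[np.argmin(curves, axis=0)]
    return SweepResult(coefficients, curves, argmin)


def split_loadings(model: PCAModel, fused: FusedMatrix):
    """Partition each loading column into its Raman and MALDI parts.

    Returns ``{"raman": (axis, p_raman x k), "maldi": (axis, p_maldi x k)}``.
    """
    if fused.block.shape[0] != model.loadings.shape[0]:
        raise ValidationError(
            f"provenance covers {fused.block.shape[0]} columns but loadings "
            f"have {model.loadings.shape[0]}"
        )
    out = {}
    for which in ("raman", "maldi"):
        sel = fused.block == which
        out[which] = (fused.channel[sel], model.loadings[sel, :])
    return out


def _grid_shape(coords: np.ndarray, min_fill: float = 0.3):
    xs = np.unique(coords[:, 0])
    ys = np.unique(coords[:, 1])
    lookup_x = {v: i for i, v in enumerate(xs)}
    lookup_y = {v: i for i, v in enumerate(ys)}
    cells = xs.size * ys.size
    if cells < coords.shape[0] or coords.shape[0] < min_fill * cells:
        raise ValidationError(
            "coordinates do not form a rectangular grid; rasterize with an "
            "explicit pitch first"
        )
    cols = np.array([lookup_x[v] for v in coords[:, 0]])
    rows = np.array([lookup_y[v] for v in coords[:, 1]])
    return rows, cols, (ys.size, xs.size)


def rgb_composite(model: PCAModel, coords: np.ndarray,
                  pcs=(0, 1, 2), missing_value: float = 0.5) -> np.ndarray:
    """False-color composite of three PC score maps.

    Each selected component is clipped to its 2nd-98th percentile range and
    min-max scaled to [0, 1]; constant channels map to 0.5.  Grid positions
    without a pixel are rendered neutral gray.  Returns an H x W x 3 array.
    """
    pcs = tuple(int(p) for p in pcs)
    if len(pcs) != 3:
        raise ParameterError("pcs must name exactly 3 components")
    if max(pcs) >= model.n_components or min(pcs) < 0:
        raise ParameterError(f"pcs {pcs} out of range for k={model.n_components}")
    coords = np.asarray(coords, dtype=float)
    rows, cols, (h, w) = _grid_shape(coords)
    img = np.full((h, w, 3), missing_value)
    for ch, pc in enumerate(pcs):
        v = model.scores[:, pc]
        lo, hi = np.percentile(v, [2.0, 98.0])
        v = np.clip(v, lo, hi)
        if hi > lo:
            v = (v - lo) / (hi - lo)
        else:
            v = np.full_like(v, 0.5)
        img[rows, cols, ch] = v
    return img


def cross_correlation(a: SpectralMap, b: SpectralMap) -> np.ndarray:
    """Pearson correlation across pixels between every channel pair.

    Entry (i, j) correlates channel i of ``a`` with channel j of ``b``.
    Constant channels produce NaN (a missing-value flag), not an error.
    """
    if a.n_pixels != b.n_pixels or not np.allclose(a.coords, b.coords):
        raise ValidationError("maps are not pixel-aligned")
    n = a.n_pixels
    if n < 3:
        raise ValidationError("need at least 3 shared pixels")
    xa = a.intensities - a.intensities.mean(axis=0)
    xb = b.intensities - b.intensities.mean(axis=0)
    sa = np.sqrt(np.sum(xa * xa, axis=0))
    sb = np.sqrt(np.sum(xb * xb, axis=0))
    const_a = np.ptp(a.intensities, axis=0) == 0
    const_b = np.ptp(b.intensities, axis=0) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xa.T @ xb) / np.outer(sa, sb)
    r[const_a | (sa == 0), :] = np.nan
    r[:, const_b | (sb == 0)] = np.nan
    return r
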