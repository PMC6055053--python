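"""Landmark-based affine co-registration and nearest-grid-point resampling.

The Raman map's coordinates are transformed into the MALDI frame with an
affine fitted by least squares to paired landmarks; every transformed source
pixel is then assigned to its nearest target grid point and spectra assigned
to the same target point are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ParameterError, ValidationError
from .io import LandmarkSet, SpectralMap

__all__ = ["Affine2D", "fit_affine", "apply_affine", "resample_to_grid", "drop_missing"]


@dataclass
class Affine2D:
    """Planar affine transform x -> A x + t (units: um)."""

    linear: np.ndarray
    translation: np.ndarray
    fit_residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        if abs(np.linalg.det(self.linear)) < 1e-12:
            raise ValidationError("affine linear part is singular")
        self.fit_residuals = np.asarray(self.fit_residuals, dtype=float)

    def inverse(self) -> "Affine2D":
        inv = np.linalg.inv(self.linear)
        return Affine2D(inv, -inv @ self.translation)

    @classmethod
    def identity(cls) -> "Affine2D":
        return cls(np.eye(2), np.zeros(2))


def fit_affine(landmarks: LandmarkSet) -> Affine2D:
    """Least-squares affine minimizing sum ||A src + t - tgt||^2.

    With exactly 3 non-collinear landmarks the system is exactly determined
    and the residuals are zero.
    """
    src = landmarks.source_xy
    tgt = landmarks.target_xy
    design = np.hstack([src, np.ones((src.shape[0], 1))])
    coef, *_ = np.linalg.lstsq(design, tgt, rcond=None)
    linear = coef[:2].T
    translation = coef[2]
    pred = src @ linear.T + translation
    residuals = np.linalg.norm(pred - tgt, axis=1)
    return Affine2D(linear, translation, residuals)


def apply_affine(t: Affine2D, coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    return coords @ t.linear.T + t.translation


def resample_to_grid(source: SpectralMap, target_coords: np.ndarray,
                     t: Affine2D | None = None,
                     max_distance: float | None = None):
    """Assign transformed source pixels to nearest target points and average.

    Each source pixel (after applying ``t``) goes to its Euclidean-nearest
    target point; exact ties go to the target that comes first in
    lexicographic (y, x) order.  Target points receiving no source pixel are
    flagged missing (``meta["missing_mask"]``) and should be excluded from
    fusion.  Returns the resampled map (rows ordered like ``target_coords``)
    and the per-target assignment counts.
    """
    target_coords = np.asarray(target_coords, dtype=float)
    if target_coords.ndim != 2 or target_coords.shape[1] != 2:
        raise ParameterError("target_coords must be m x 2")
    if np.unique(target_coords, axis=0).shape[0] != target_coords.shape[0]:
        raise ValidationError("target coordinates must be distinct")
    if t is None:
        t = Affine2D.identity()
    src_xy = apply_affine(t, source.coords)

    # lexicographic (y, x) target order so argmin's first-minimum rule
    # implements the documented deterministic tie-break
    lex = np.lexsort((target_coords[:, 0], target_coords[:, 1]))
    dists = cdist(src_xy, target_coords[lex])
    nearest_sorted = np.argmin(dists, axis=1)
    nearest = lex[nearest_sorted]
    mind = dists[np.arange(src_xy.shape[0]), nearest_sorted]

    keep = np.ones(src_xy.shape[0], dtype=bool)
    if max_distance is not None:
        keep = mind <= max_distance

    m = target_coords.shape[0]
    counts = np.bincount(nearest[keep], minlength=m)
    if not counts.any():
        raise ValidationError("grids do not overlap: no source pixel was assigned")
    sums = np.zeros((m, source.n_channels))
    np.add.at(sums, nearest[keep], source.intensities[keep])
    out = np.zeros_like(sums)
    nonzero = counts > 0
    out[nonzero] = sums[nonzero] / counts[nonzero, None]

    meta = dict(source.meta)
    meta["resampled"] = True
    meta["missing_mask"] = ~nonzero
    meta["counts"] = counts
    resampled = SpectralMap(out, source.axis.copy(), target_coords.copy(),
                            source.modality, meta)
    return resampled, counts


def drop_missing(*maps: SpectralMap):
    """Remove pixels flagged missing in any of the given aligned maps."""
    n = maps[0].n_pixels
    keep = np.ones(n, dtype=bool)
    for m in maps:
        if m.n_pixels != n:
            raise ValidationError("maps are not pixel-aligned")
        mask = m.meta.get("missing_mask")
        if mask is not None:
            keep &= ~np.asarray(mask, dtype=bool)
    out = []
    for m in maps:
        sel = m.select_pixels(keep)
        sel.meta.pop("missing_mask", None)
        out.append(sel)
    return tuple(out) if len(out) > 1 else out[0]
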