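"""Block weighting and column-wise concatenation at the data fusion center.

Two preprocessed, pixel-aligned blocks are combined into one matrix.  To
balance their influence on a subsequent PCA the second (MALDI) block is
multiplied by the ratio of the blocks' matrix l1-norms (sums of absolute
values of all entries), after which both blocks have equal l1-norms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ValidationError
from .io import SpectralMap

__all__ = ["FusedMatrix", "l1_weight", "fuse_blocks", "slice_block"]


@dataclass
class FusedMatrix:
    """Column-concatenated blocks with per-column provenance."""

    matrix: np.ndarray            # n_pixels x (p_raman + p_maldi)
    block: np.ndarray             # per-column tag, "raman" or "maldi"
    channel: np.ndarray           # per-column original channel value
    w: float                      # weight applied to the maldi block
    coords: np.ndarray            # n_pixels x 2, um

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.block = np.asarray(self.block)
        self.channel = np.asarray(self.channel, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        p = self.matrix.shape[1]
        if self.block.shape[0] != p or self.channel.shape[0] != p:
            raise ValidationError("provenance length must equal column count")
        if self.coords.shape != (self.matrix.shape[0], 2):
            raise ValidationError("coords must be n_pixels x 2")
        if not self.w > 0:
            raise ParameterError("weight w must be positive")

    @property
    def n_pixels(self) -> int:
        return self.matrix.shape[0]


def matrix_l1(x: np.ndarray) -> float:
    """Sum of absolute values of all entries."""
    return float(np.abs(np.asarray(x, dtype=float)).sum())


def l1_weight(a: np.ndarray, b: np.ndarray) -> float:
    """Weighting coefficient w = ||A||_1 / ||B||_1, so ||w B||_1 = ||A||_1."""
    norm_b = matrix_l1(b)
    if norm_b == 0:
        raise ValidationError("second block has zero l1-norm")
    norm_a = matrix_l1(a)
    if norm_a == 0:
        raise ValidationError("first block has zero l1-norm")
    return norm_a / norm_b


def fuse_blocks(a: SpectralMap, b: SpectralMap, w: float) -> FusedMatrix:
    """Concatenate ``[A | w B]`` column-wise.

    Both maps must share the pixel set and ordering (i.e. be
    post-co-registration, with missing-flagged pixels already dropped).
    """
    if not w > 0:
        raise ParameterError("weight must be positive")
    if a.n_pixels != b.n_pixels or not np.allclose(a.coords, b.coords):
        mism = _coord_mismatch(a, b)
        raise ValidationError(f"pixel sets differ between blocks: {mism}")
    matrix = np.hstack([a.intensities, w * b.intensities])
    block = np.array(["raman"] * a.n_channels + ["maldi"] * b.n_channels)
    channel = np.concatenate([a.axis, b.axis])
    return FusedMatrix(matrix, block, channel, float(w), a.coords.copy())


def _coord_mismatch(a: SpectralMap, b: SpectralMap) -> str:
    if a.n_pixels != b.n_pixels:
        return f"{a.n_pixels} vs {b.n_pixels} pixels"
    bad = np.flatnonzero(~np.all(np.isclose(a.coords, b.coords), axis=1))[:5]
    pairs = [f"{tuple(a.coords[i])} vs {tuple(b.coords[i])}" for i in bad]
    return "; ".join(pairs)


def slice_block(fused: FusedMatrix, which: str) -> np.ndarray:
    """Extract one block (including its weighting) from the fused matrix."""
    if which not in ("raman", "maldi"):
        raise ParameterError("which must be 'raman' or 'maldi'")
    return fused.matrix[:, fused.block == which]
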