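import numpy as np
import pytest

from spectrafuse import SpectralMap, fit_affine, fuse, l1_weight
from spectrafuse.config import merge_config
from spectrafuse import coregister
from spectrafuse.pipeline import preprocess_maldi, preprocess_raman
from spectrafuse.synthetic import generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def grid_coords(nx, ny, pitch=25.0):
    gx, gy = np.meshgrid(np.arange(nx) * pitch, np.arange(ny) * pitch)
    return np.column_stack([gx.ravel(), gy.ravel()])


@pytest.fixture
def small_map(rng):
    """A 12-pixel, 20-channel Raman map with smooth spectra."""
    coords = grid_coords(4, 3)
    axis = np.linspace(800.0, 1800.0, 20)
    base = np.exp(-0.5 * ((axis - 1200.0) / 150.0) ** 2)
    intens = np.outer(rng.uniform(0.5, 2.0, 12), base) + 0.01
    return SpectralMap(intens, axis, coords, "raman")


@pytest.fixture(scope="session")
def phantom():
    """Default phantom at seed 42 (the acceptance configuration)."""
    return generate_phantom(seed=42)


@pytest.fixture(scope="session")
def phantom_blocks(phantom):
    """Fully preprocessed, pixel-aligned Raman and MALDI blocks (+context).

    Computed once per session; several evaluation and acceptance tests share
    it to stay inside the runtime budget.
    """
    raman_map, maldi_map, truth = phantom
    cfg = merge_config(None)
    transform = fit_affine(truth.landmarks)
    resampled, counts = coregister.resample_to_grid(
        raman_map, maldi_map.coords, transform)
    raman_proc = preprocess_raman(resampled, cfg)
    maldi_proc, table, phase = preprocess_maldi(maldi_map, cfg)
    keep = ~np.asarray(resampled.meta["missing_mask"])
    raman_proc = raman_proc.select_pixels(keep)
    maldi_proc = maldi_proc.select_pixels(keep)
    w = l1_weight(raman_proc.intensities, maldi_proc.intensities)
    return {
        "truth": truth,
        "raman": raman_proc,
        "maldi": maldi_proc,
        "keep": keep,
        "w": w,
        "counts": counts,
        "bin_table": table,
        "phase": phase,
        "config": cfg,
    }
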