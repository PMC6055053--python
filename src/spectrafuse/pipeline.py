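"""End-to-end driver: coregister -> preprocess -> weight -> fuse -> evaluate.

Co-registration runs first (both modalities are brought onto the MALDI
grid before any spectral preprocessing), then each modality is preprocessed
with its fixed stage order, the MALDI block is weighted by the l1-norm
ratio, the blocks are concatenated, and the fused matrix is analyzed with a
mean-centered PCA.  The run report collects every block norm, the weighting
coefficient and the explained-variance curves, and is fully deterministic
for a fixed config (no timestamps).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import baseline, coregister, evaluate, fuse, maldi, raman
from .config import merge_config
from .errors import PipelineError
from .io import LandmarkSet, SpectralMap, write_spectral_map

__all__ = ["run_pipeline", "preprocess_raman", "preprocess_maldi"]

log = logging.getLogger("spectrafuse")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("preprocess-raman")
def preprocess_raman(m: SpectralMap, cfg: dict) -> SpectralMap:
    """Calibration (axis interpolation) -> spike removal -> SNIP -> normalize."""
    rcfg, scfg = cfg["raman"], cfg["snip"]
    if rcfg["target_axis"] is not None:
        start, stop, step = rcfg["target_axis"]
        target = np.arange(start, stop + 0.5 * step, step)
        m = raman.interpolate_axis(m, target)
        log.info("raman: interpolated to %d channels", m.n_channels)
    mask = raman.detect_spikes(m, z_threshold=rcfg["spike_z"])
    m = raman.remove_spikes(m, mask)
    log.info("raman: removed %d spike cells", mask.n_flagged)
    params = baseline.SnipParams(scfg["raman_window"], scfg["raman_lls"], scfg["order"])
    m = baseline.subtract_baseline(m, params)
    m = raman.normalize(m, rcfg["norm"])
    log.info("raman: %d x %d, l1 norm %.6g", m.n_pixels, m.n_channels,
             float(np.abs(m.intensities).sum()))
    return m


@_stage("preprocess-maldi")
def preprocess_maldi(m: SpectralMap, cfg: dict):
    """SNIP background -> phase correction -> peak picking -> binning -> TIC."""
    mcfg, scfg = cfg["maldi"], cfg["snip"]
    params = baseline.SnipParams(scfg["maldi_window"], scfg["maldi_lls"], scfg["order"])
    m = baseline.subtract_baseline(m, params)
    corrected, phase = maldi.phase_correct(
        m, max_shift=mcfg["max_shift"], anchor_quantile=mcfg["anchor_quantile"],
        model=mcfg["phase_model"],
    )
    log.info("maldi: phase anchors %s, offset range [%.4g, %.4g] Da",
             np.round(phase.anchors, 3).tolist(),
             phase.offsets.min(), phase.offsets.max())
    peak_lists = [
        maldi.pick_peaks(corrected.axis, corrected.intensities[i],
                         snr=mcfg["snr"], pixel_id=i)
        for i in range(corrected.n_pixels)
    ]
    binned, table = maldi.bin_peaks(peak_lists, mcfg["tolerance_ppm"],
                                    coords=corrected.coords)
    binned.meta.update(corrected.meta)
    log.info("maldi: %d bins after %g ppm binning", table.n_bins, mcfg["tolerance_ppm"])
    normalized = maldi.normalize_ms(binned, mcfg["norm"])
    return normalized, table, phase


def run_pipeline(raman_map: SpectralMap, maldi_map: SpectralMap,
                 landmarks: LandmarkSet, config: dict | None = None,
                 outdir=None) -> dict:
    """Run the full fusion pipeline and return the run report (a dict).

    ``config`` is merged over the package defaults; unknown keys raise.  If
    ``outdir`` is given the report, curves, correlation matrix, composites
    and processed blocks are written there.
    """
    cfg = merge_config(config) if not _is_merged(config) else config
    report: dict = {"config": cfg}

    # --- stage 1: co-registration (before spectral preprocessing) ----------
    transform = _fit(landmarks)
    resampled, counts = coregister.resample_to_grid(
        raman_map, maldi_map.coords, transform,
        max_distance=cfg["coregister"]["max_distance"])
    log.info("coregister: %d/%d target pixels covered, median count %d",
             int((counts > 0).sum()), counts.size, int(np.median(counts[counts > 0])))
    report["coregister"] = {
        "landmark_rms_um": float(np.sqrt(np.mean(transform.fit_residuals ** 2))),
        "covered_pixels": int((counts > 0).sum()),
        "n_target_pixels": int(counts.size),
        "median_count": int(np.median(counts[counts > 0])),
    }

    # --- stage 2: per-modality preprocessing -------------------------------
    raman_proc = preprocess_raman(resampled, cfg)
    maldi_proc, table, phase = preprocess_maldi(maldi_map, cfg)
    missing = resampled.meta["missing_mask"]
    keep = ~np.asarray(missing, dtype=bool)
    raman_proc = raman_proc.select_pixels(keep)
    maldi_proc = maldi_proc.select_pixels(keep)
    report["preprocess"] = {
        "raman_shape": [raman_proc.n_pixels, raman_proc.n_channels],
        "maldi_shape": [maldi_proc.n_pixels, maldi_proc.n_channels],
        "n_bins": int(table.n_bins),
        "phase_offset_rms_da": float(np.sqrt(np.mean(phase.offsets ** 2))),
        "pixels_dropped": int((~keep).sum()),
    }

    # --- stage 3: weighting ------------------------------------------------
    weight_cfg = cfg["fuse"]["weight"]
    w_auto = fuse.l1_weight(raman_proc.intensities, maldi_proc.intensities)
    w = w_auto if weight_cfg == "auto" else float(weight_cfg)
    report["weighting"] = {
        "w": w,
        "w_auto": w_auto,
        "raman_l1": fuse.matrix_l1(raman_proc.intensities),
        "maldi_l1": fuse.matrix_l1(maldi_proc.intensities),
    }

    # --- stage 4: fusion ---------------------------------------------------
    fused = fuse.fuse_blocks(raman_proc, maldi_proc, w)
    report["fusion"] = {
        "n_pixels": fused.n_pixels,
        "n_columns": fused.matrix.shape[1],
        "raman_block_l1": fuse.matrix_l1(fuse.slice_block(fused, "raman")),
        "maldi_block_l1": fuse.matrix_l1(fuse.slice_block(fused, "maldi")),
    }

    # --- stage 5: evaluation -----------------------------------------------
    k = min(cfg["evaluate"]["components"], fused.n_pixels - 1,
            fused.matrix.shape[1])
    model = evaluate.pca(fused.matrix, k)
    report["pca"] = {
        "k": k,
        "explained": model.explained.tolist(),
        "cumulative": model.cumulative.tolist(),
    }
    sweep_cfg = cfg["evaluate"]["sweep"]
    sweep = None
    if sweep_cfg is not None:
        lo, hi = int(sweep_cfg[0]), int(sweep_cfg[1])
        coeffs = np.arange(lo, hi + 1, dtype=float)
        sweep = evaluate.weight_sweep(raman_proc, maldi_proc, coeffs, k=k)
        report["sweep"] = {
            "coefficients": sweep.coefficients.tolist(),
            "curves": sweep.curves.tolist(),
            "argmin_per_k": sweep.argmin_per_k.tolist(),
        }

    if outdir is not None:
        _write_outputs(Path(outdir), cfg, report, raman_proc, maldi_proc,
                       fused, model, sweep)
    return report


def _is_merged(config) -> bool:
    from .config import DEFAULT_CONFIG
    return isinstance(config, dict) and set(config) == set(DEFAULT_CONFIG)


@_stage("coregister")
def _fit(landmarks: LandmarkSet):
    return coregister.fit_affine(landmarks)


def _write_outputs(outdir: Path, cfg, report, raman_proc, maldi_proc,
                   fused, model, sweep) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import yaml

    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    write_spectral_map(raman_proc, outdir / "raman_processed.csv")
    write_spectral_map(maldi_proc, outdir / "maldi_processed.csv")

    header = ",".join(f"PC{i + 1}" for i in range(model.n_components))
    np.savetxt(outdir / "cumulative_curve.csv",
               model.cumulative[None, :], delimiter=",", header=header,
               comments="")
    corr = evaluate.cross_correlation(raman_proc, maldi_proc)
    np.savetxt(outdir / "cross_correlation.csv", corr, delimiter=",")

    pcs = [p - 1 for p in cfg["evaluate"]["pcs"]]
    if max(pcs) < model.n_components:
        img = evaluate.rgb_composite(model, fused.coords, pcs)
        plt.imsave(outdir / "composite_fused.png", img, origin="lower")
    if sweep is not None:
        np.savetxt(outdir / "sweep_curves.csv", sweep.curves, delimiter=",")
        fig, ax = plt.subplots(figsize=(6, 4))
        extent = [1, sweep.curves.shape[1],
                  sweep.coefficients[0], sweep.coefficients[-1]]
        ax.imshow(sweep.curves, aspect="auto", origin="lower", extent=extent)
        ax.set_xlabel("number of PCs")
        ax.set_ylabel("weighting coefficient")
        fig.savefig(outdir / "sweep_surface.png", dpi=120)
        plt.close(fig)
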