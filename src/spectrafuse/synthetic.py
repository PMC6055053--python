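"""Phantom generator: paired Raman/MALDI maps with known ground truth.

The phantom emulates a correlated imaging experiment: a Raman map on a
25 um grid and a MALDI map on a 75 um grid, rotated/translated relative to
each other by a known affine, sharing smooth spatial abundance fields.  One
component (the "lipid" component) has no Raman endmember at all and shows up
only as a set of low-intensity MALDI ions with isotope envelopes — by
default its signal energy is a small fraction of the Raman block's, so an
unweighted fusion buries it while an l1-ratio-weighted fusion exposes it.

Corrupting effects included: per-pixel polynomial fluorescence baselines,
Gaussian noise and sparse cosmic spikes (Raman); Gaussian peak shapes with
mass-dependent width, isotope envelopes, per-pixel m/z jitter, an
exponentially decaying chemical background, multiplicative TIC variation and
Poisson-like noise (MALDI).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coregister import Affine2D, apply_affine
from .errors import ParameterError, ValidationError
from .io import LandmarkSet, SpectralMap

__all__ = ["PhantomConfig", "PhantomTruth", "generate_phantom", "score_recovery"]

ISOTOPE_SPACING = 1.0034
DEFAULT_ENVELOPE = (1.0, 0.6, 0.2)


@dataclass
class PhantomConfig:
    # grids (pitches follow the 25 um Raman / 75 um MALDI geometry)
    maldi_shape: tuple = (16, 16)      # (ny, nx)
    maldi_pitch: float = 75.0
    raman_pitch: float = 25.0
    # channel axes
    raman_axis: tuple = (602.0, 1798.0, 2.0)     # start, stop, step (cm^-1)
    maldi_axis: tuple = (598.0, 902.0, 0.05)     # start, stop, step (Da)
    # known Raman -> MALDI transform
    rotation_deg: float = 2.0
    translation: tuple = (40.0, -25.0)
    # components: per-component Raman bands (center, width, height); broad
    # secondary bands widen spectral support, which raises the l1/l2 ratio
    # of the normalized spectra and with it the fused weighting coefficient
    raman_bands: tuple = (
        ((1004.0, 8.0, 1.0), (1340.0, 12.0, 0.5), (1660.0, 14.0, 0.8),
         (850.0, 30.0, 0.4), (1240.0, 40.0, 0.5), (1580.0, 35.0, 0.4),
         (1130.0, 25.0, 0.3)),
        ((1450.0, 12.0, 0.9), (1260.0, 10.0, 0.4), (780.0, 10.0, 0.3),
         (950.0, 35.0, 0.4), (1390.0, 30.0, 0.4), (1700.0, 30.0, 0.3),
         (1060.0, 28.0, 0.3)),
        ((1090.0, 10.0, 2.6), (1740.0, 12.0, 2.0), (930.0, 10.0, 1.3),
         (700.0, 30.0, 1.0), (1490.0, 35.0, 1.0), (1620.0, 25.0, 0.8)),
        (),                                       # lipid: MALDI-only
    )
    # per-component MALDI ions (monoisotopic m/z, base intensity); the third
    # component is Raman-only so the unweighted PC3 stays a pure Raman axis
    maldi_ions: tuple = (
        ((703.57, 0.3),),
        ((760.59, 0.25),),
        (),
        ((734.57, 1.0), (772.53, 0.7), (810.60, 0.5)),
    )
    matrix_ions: tuple = ((650.15, 6.0), (690.21, 4.0))   # spatially flat
    isotope_envelope: tuple = DEFAULT_ENVELOPE
    lipid_component: int = 3
    # energy budget (l1 energies of noiseless signals, relative to Raman's)
    maldi_energy_ratio: float = 0.2    # non-lipid MALDI signal vs Raman signal
    lipid_energy_ratio: float = 0.01   # lipid MALDI signal vs Raman signal
    # noise / corruption levels
    raman_signal_scale: float = 1000.0
    raman_noise: float = 4.0
    raman_baseline_scale: float = 400.0
    spike_rate: float = 3e-4
    spike_amp: tuple = (30.0, 90.0)    # in raman_noise units
    mz_jitter_sd: float = 0.03
    peak_width: tuple = (0.06, 0.03)   # sigma at 600 Da, growth over 300 Da
    chem_bg_amp: float = 0.3           # relative to mean per-channel signal
    chem_bg_decay: float = 120.0       # Da
    tic_variation_sd: float = 0.15     # lognormal sigma
    maldi_counts: float = 3e6          # expected total counts per spectrum
    n_blobs: int = 4

    def __post_init__(self) -> None:
        if len(self.raman_bands) != len(self.maldi_ions):
            raise ParameterError("raman_bands and maldi_ions must have the same K")
        if len(self.raman_bands) < 2:
            raise ParameterError("need at least 2 components")
        if min(self.maldi_shape) < 8:
            raise ParameterError("maldi grid must be at least 8 x 8")
        if not 0 <= self.lipid_component < len(self.raman_bands):
            raise ParameterError("lipid_component out of range")

    @property
    def n_components(self) -> int:
        return len(self.raman_bands)


@dataclass
class PhantomTruth:
    component_maps: np.ndarray      # K x ny x nx abundances on the MALDI grid
    component_values: np.ndarray    # K x n_maldi_pixels (row-major y, x order)
    raman_endmembers: np.ndarray    # K x n_raman_channels
    maldi_endmembers: list          # K lists of (mz, envelope, base intensity)
    landmarks: LandmarkSet
    transform: Affine2D
    lipid_component: int
    seed: int


def _axis(spec) -> np.ndarray:
    start, stop, step = spec
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def _pseudo_voigt(axis: np.ndarray, center: float, width: float,
                  height: float, eta: float = 0.3) -> np.ndarray:
    u = (axis - center) / width
    lorentz = 1.0 / (1.0 + u * u)
    gauss = np.exp(-0.5 * u * u * 4.0 * math.log(2.0))
    return height * (eta * lorentz + (1.0 - eta) * gauss)


def _smooth_disc(xy, center, radius, softness=40.0):
    d = np.linalg.norm(xy - np.asarray(center), axis=1)
    return 0.5 * (1.0 - np.tanh((d - radius) / softness))


def _smooth_stripe(xy, y0, halfwidth, softness=40.0):
    d = np.abs(xy[:, 1] - y0)
    return 0.5 * (1.0 - np.tanh((d - halfwidth) / softness))


def _make_fields(cfg: PhantomConfig, rng: np.random.Generator, extent):
    """Per-component smooth abundance functions of MALDI-frame (x, y)."""
    (x0, x1), (y0, y1) = extent
    span = max(x1 - x0, y1 - y0)

    def blob_fn(local_rng):
        centers = np.column_stack([
            local_rng.uniform(x0, x1, cfg.n_blobs),
            local_rng.uniform(y0, y1, cfg.n_blobs),
        ])
        widths = local_rng.uniform(0.15 * span, 0.35 * span, cfg.n_blobs)
        weights = local_rng.uniform(0.4, 1.0, cfg.n_blobs)

        def f(xy):
            out = np.zeros(xy.shape[0])
            for c, w, a in zip(centers, widths, weights):
                d2 = np.sum((xy - c) ** 2, axis=1)
                out += a * np.exp(-0.5 * d2 / (w * w))
            return out

        return f

    fields = []
    for k in range(cfg.n_components):
        base = blob_fn(rng)
        if k == 1:
            disc = ((x0 + 0.3 * (x1 - x0)), (y0 + 0.65 * (y1 - y0)))
            extra = lambda xy, c=disc: 0.8 * _smooth_disc(xy, c, 0.18 * span)
        elif k == cfg.lipid_component:
            stripe_y = y0 + 0.3 * (y1 - y0)
            disc = ((x0 + 0.72 * (x1 - x0)), (y0 + 0.72 * (y1 - y0)))
            extra = lambda xy, yy=stripe_y, c=disc: (
                0.9 * _smooth_stripe(xy, yy, 0.1 * span)
                + 0.7 * _smooth_disc(xy, c, 0.12 * span)
            )
        else:
            extra = lambda xy: 0.0
        fields.append((base, extra))

    def evaluate(xy):
        vals = np.empty((cfg.n_components, xy.shape[0]))
        for k, (base, extra) in enumerate(fields):
            vals[k] = base(xy) + extra(xy)
        return vals

    return evaluate


def _decorrelate_lipid(cfg: PhantomConfig, a_maldi, a_raman):
    """Regress the shared fields (plus intercept) out of the lipid field.

    The end-to-end recovery experiment needs the MALDI-only component's map
    to be spatially independent of the shared components; random blob
    placement alone leaves chance correlations of ~0.5 on small grids.  The
    same linear combination is applied on both grids (a linear combination
    of smooth fields stays smooth); negative residuals are clipped to 0.
    """
    lip = cfg.lipid_component
    others = [k for k in range(cfg.n_components) if k != lip]
    joint = np.hstack([a_maldi, a_raman])
    design = np.vstack([joint[others], np.ones(joint.shape[1])]).T
    beta, *_ = np.linalg.lstsq(design, joint[lip], rcond=None)
    for arr in (a_maldi, a_raman):
        resid = arr[lip] - beta[:-1] @ arr[others] - beta[-1]
        arr[lip] = np.clip(resid, 0.0, None)
    return a_maldi, a_raman


def generate_phantom(config: PhantomConfig | None = None, seed: int = 42):
    """Generate (raman map, raw-profile maldi map, truth); deterministic in seed."""
    cfg = config or PhantomConfig()
    rng = np.random.default_rng(seed)

    ny, nx = cfg.maldi_shape
    gx, gy = np.meshgrid(np.arange(nx) * cfg.maldi_pitch,
                         np.arange(ny) * cfg.maldi_pitch)
    maldi_xy = np.column_stack([gx.ravel(), gy.ravel()])  # row-major (y, x)

    theta = math.radians(cfg.rotation_deg)
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    transform = Affine2D(rot, np.asarray(cfg.translation, dtype=float))
    inverse = transform.inverse()

    # Raman grid in its own frame, covering the MALDI extent plus a margin
    margin = 1.2 * cfg.maldi_pitch
    ext_x = (-margin, (nx - 1) * cfg.maldi_pitch + margin)
    ext_y = (-margin, (ny - 1) * cfg.maldi_pitch + margin)
    corners = np.array([[ext_x[0], ext_y[0]], [ext_x[1], ext_y[0]],
                        [ext_x[0], ext_y[1]], [ext_x[1], ext_y[1]]])
    src_corners = apply_affine(inverse, corners)
    rx0, ry0 = np.floor(src_corners.min(axis=0) / cfg.raman_pitch) * cfg.raman_pitch
    rx1, ry1 = np.ceil(src_corners.max(axis=0) / cfg.raman_pitch) * cfg.raman_pitch
    rxs = np.arange(rx0, rx1 + 0.5 * cfg.raman_pitch, cfg.raman_pitch)
    rys = np.arange(ry0, ry1 + 0.5 * cfg.raman_pitch, cfg.raman_pitch)
    rgx, rgy = np.meshgrid(rxs, rys)
    raman_xy = np.column_stack([rgx.ravel(), rgy.ravel()])
    raman_xy_in_maldi = apply_affine(transform, raman_xy)

    # abundance fields (defined in the MALDI frame)
    evaluate = _make_fields(cfg, rng, (ext_x, ext_y))
    a_maldi = evaluate(maldi_xy)
    a_raman = evaluate(raman_xy_in_maldi)
    a_maldi, a_raman = _decorrelate_lipid(cfg, a_maldi, a_raman)
    # standardize each field to a fixed spread so component variances (and
    # therefore the PCA eigenvalue layout) are stable across seeds
    joint = np.hstack([a_maldi, a_raman])
    mu = joint.mean(axis=1)
    sd = joint.std(axis=1)
    sd[sd == 0] = 1.0
    a_maldi = np.clip(0.5 + 0.22 * (a_maldi - mu[:, None]) / sd[:, None], 0.0, 1.0)
    a_raman = np.clip(0.5 + 0.22 * (a_raman - mu[:, None]) / sd[:, None], 0.0, 1.0)

    # ----- Raman block -----------------------------------------------------
    raman_axis = _axis(cfg.raman_axis)
    endmembers = np.zeros((cfg.n_components, raman_axis.size))
    for k, bands in enumerate(cfg.raman_bands):
        for center, width, height in bands:
            endmembers[k] += _pseudo_voigt(raman_axis, center, width, height)
    raman_signal = cfg.raman_signal_scale * (a_raman.T @ endmembers)
    e_raman = float(np.abs(raman_signal).sum())

    n_r = raman_xy.shape[0]
    u = np.linspace(0.0, 1.0, raman_axis.size)
    c0 = rng.uniform(0.4, 1.0, n_r)
    c1 = rng.uniform(-0.3, 0.6, n_r)
    c2 = rng.uniform(-0.3, 0.4, n_r)
    baseline = cfg.raman_baseline_scale * (
        c0[:, None] + c1[:, None] * u + c2[:, None] * u * u + 0.35
    )
    raman_raw = raman_signal + baseline
    raman_raw += rng.normal(0.0, cfg.raman_noise, raman_raw.shape)
    spikes = rng.random(raman_raw.shape) < cfg.spike_rate
    amps = rng.uniform(*cfg.spike_amp, size=int(spikes.sum())) * cfg.raman_noise
    raman_raw[spikes] += amps
    np.clip(raman_raw, 0.0, None, out=raman_raw)  # raw signal is non-negative
    raman_map = SpectralMap(raman_raw, raman_axis, raman_xy, "raman",
                            {"phantom_seed": seed})

    # ----- MALDI block -----------------------------------------------------
    maldi_axis = _axis(cfg.maldi_axis)
    n_m = maldi_xy.shape[0]
    envelope = np.asarray(cfg.isotope_envelope)
    jitter = np.clip(rng.normal(0.0, cfg.mz_jitter_sd, n_m), -0.1, 0.1)

    def add_peaks(target, mz0, amplitudes):
        """Add one ion (all isotopes) for every pixel; per-pixel jitter."""
        w0, wg = cfg.peak_width
        for iso, frac in enumerate(envelope):
            mz = mz0 + iso * ISOTOPE_SPACING
            sigma = w0 + wg * (mz - cfg.maldi_axis[0]) / 300.0
            centers = mz + jitter                      # (n_m,)
            lo = np.searchsorted(maldi_axis, mz - 0.15 - 6 * sigma)
            hi = np.searchsorted(maldi_axis, mz + 0.15 + 6 * sigma)
            seg = maldi_axis[lo:hi]
            prof = np.exp(-0.5 * ((seg[None, :] - centers[:, None]) / sigma) ** 2)
            target[:, lo:hi] += amplitudes[:, None] * frac * prof

    signal_nonlipid = np.zeros((n_m, maldi_axis.size))
    signal_lipid = np.zeros_like(signal_nonlipid)
    for k, ions in enumerate(cfg.maldi_ions):
        dest = signal_lipid if k == cfg.lipid_component else signal_nonlipid
        for mz0, base in ions:
            add_peaks(dest, mz0, base * a_maldi[k])
    matrix_levels = 1.0 + rng.normal(0.0, 0.005, (n_m, len(cfg.matrix_ions)))
    for j, (mz0, base) in enumerate(cfg.matrix_ions):
        add_peaks(signal_nonlipid, mz0, base * matrix_levels[:, j])

    # energy budget relative to the Raman signal block
    e_nl = float(np.abs(signal_nonlipid).sum())
    e_lip = float(np.abs(signal_lipid).sum())
    if e_nl > 0:
        signal_nonlipid *= cfg.maldi_energy_ratio * e_raman / e_nl
    if e_lip > 0:
        signal_lipid *= cfg.lipid_energy_ratio * e_raman / e_lip
    maldi_signal = signal_nonlipid + signal_lipid

    mean_level = maldi_signal.mean()
    bg = (cfg.chem_bg_amp * mean_level
          * np.exp(-(maldi_axis - maldi_axis[0]) / cfg.chem_bg_decay))
    tic_var = np.exp(rng.normal(0.0, cfg.tic_variation_sd, n_m))
    expected = (maldi_signal + bg[None, :]) * tic_var[:, None]
    # Poisson-like shot noise: draw counts at a scale set by maldi_counts
    scale = cfg.maldi_counts / max(expected.sum(axis=1).mean(), 1e-300)
    maldi_raw = rng.poisson(expected * scale).astype(float) / scale
    maldi_map = SpectralMap(maldi_raw, maldi_axis, maldi_xy, "maldi",
                            {"phantom_seed": seed})

    # ----- landmarks (exact, noiseless) ------------------------------------
    lx = np.array([rxs[1], rxs[-2], rxs[1], rxs[-2], rxs[len(rxs) // 2], rxs[len(rxs) // 3]])
    ly = np.array([rys[1], rys[1], rys[-2], rys[-2], rys[len(rys) // 2], rys[2 * len(rys) // 3]])
    src = np.column_stack([lx, ly])
    landmarks = LandmarkSet(src, apply_affine(transform, src))

    truth = PhantomTruth(
        component_maps=a_maldi.reshape(cfg.n_components, ny, nx),
        component_values=a_maldi,
        raman_endmembers=endmembers,
        maldi_endmembers=[
            [(mz, tuple(envelope), base) for mz, base in ions]
            for ions in cfg.maldi_ions
        ],
        landmarks=landmarks,
        transform=transform,
        lipid_component=cfg.lipid_component,
        seed=seed,
    )
    return raman_map, maldi_map, truth


def score_recovery(scores: np.ndarray, truth: PhantomTruth, k: int,
                   pixel_index: np.ndarray | None = None) -> np.ndarray:
    """Best |Pearson r| between each true component map and the first k scores.

    ``scores`` may be a PCAModel or a raw n x >=k score array.  If the
    analysis dropped pixels, ``pixel_index`` selects the surviving rows of
    the truth maps (in MALDI row-major order).
    """
    s = getattr(scores, "scores", scores)
    s = np.asarray(s, dtype=float)
    if s.ndim != 2 or s.shape[1] < k:
        raise ParameterError(f"scores must provide at least k={k} columns")
    comp = truth.component_values
    if pixel_index is not None:
        comp = comp[:, pixel_index]
    if comp.shape[1] != s.shape[0]:
        raise ValidationError(
            f"grid mismatch: truth has {comp.shape[1]} pixels, scores {s.shape[0]}"
        )
    out = np.empty(comp.shape[0])
    for i, cmap in enumerate(comp):
        rs = []
        for j in range(k):
            sd_c, sd_s = np.std(cmap), np.std(s[:, j])
            if sd_c == 0 or sd_s == 0:
                rs.append(0.0)
            else:
                rs.append(abs(np.corrcoef(cmap, s[:, j])[0, 1]))
        out[i] = max(rs)
    return out
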