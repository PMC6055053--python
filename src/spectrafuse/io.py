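"""Core data containers and file I/O for spectral maps, peak lists and landmarks.

Two text dialects are supported for maps:

``wide_csv``
    Row 1 holds the literal labels ``x,y`` followed by the channel-axis
    values (wavenumber in cm^-1 or m/z in Da).  Every following row is one
    pixel: its x, y position in micrometres and then one intensity per
    channel.  Period decimal separator, comma field separator.

``imzml``
    A minimal imzML reader/writer (continuous and processed binary modes,
    32/64-bit floats) backed by the paired ``.ibd`` file.  Pixel positions
    in imzML are 1-based grid indices; they are converted to micrometre
    coordinates using the ``pixel size x``/``pixel size y`` parameters, so a
    regular grid anchored at the origin round-trips exactly.
"""

from __future__ import annotations

import uuid
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ParameterError, ParseError, ValidationError

__all__ = [
    "SpectralMap",
    "PeakList",
    "LandmarkSet",
    "read_spectral_map",
    "write_spectral_map",
    "read_landmarks",
    "write_landmarks",
    "read_imzml_peaklists",
]

MODALITIES = ("raman", "maldi")


def _as_float_array(x, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise ValidationError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class SpectralMap:
    """A pixels x channels intensity matrix with spatial coordinates.

    Attributes
    ----------
    intensities : (n_pixels, n_channels) float array
    axis : (n_channels,) strictly increasing float array (cm^-1 or Da)
    coords : (n_pixels, 2) float array of pixel-centre x, y positions in um
    modality : ``"raman"`` or ``"maldi"``
    meta : free-form provenance dictionary (processing history, masks, ...)
    """

    intensities: np.ndarray
    axis: np.ndarray
    coords: np.ndarray
    modality: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = _as_float_array(self.intensities, "intensities", 2)
        self.axis = _as_float_array(self.axis, "axis", 1)
        self.coords = _as_float_array(self.coords, "coords", 2)
        if self.modality not in MODALITIES:
            raise ValidationError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        n, p = self.intensities.shape
        if self.axis.shape[0] != p:
            raise ValidationError(
                f"axis length {self.axis.shape[0]} != n_channels {p}"
            )
        if np.any(np.diff(self.axis) <= 0):
            raise ValidationError("axis must be strictly increasing")
        if self.coords.shape != (n, 2):
            raise ValidationError(
                f"coords shape {self.coords.shape} does not match ({n}, 2)"
            )
        uniq = np.unique(self.coords, axis=0)
        if uniq.shape[0] != n:
            raise ValidationError("duplicate pixel coordinates present")

    @property
    def n_pixels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    def with_intensities(self, intensities: np.ndarray, **meta_updates) -> "SpectralMap":
        """Copy of this map with new intensities and extra meta entries."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return replace(self, intensities=np.asarray(intensities, dtype=float), meta=meta)

    def select_pixels(self, index: np.ndarray) -> "SpectralMap":
        return replace(
            self,
            intensities=self.intensities[index],
            coords=self.coords[index],
            meta=dict(self.meta),
        )


@dataclass
class PeakList:
    """Centroided (m/z, intensity) pairs for a single pixel."""

    mz: np.ndarray
    intensity: np.ndarray
    pixel_id: int

    def __post_init__(self) -> None:
        self.mz = _as_float_array(self.mz, "mz", 1)
        self.intensity = _as_float_array(self.intensity, "intensity", 1)
        if self.mz.shape != self.intensity.shape:
            raise ValidationError("mz and intensity must have the same length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValidationError("mz must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValidationError("intensities must be non-negative")
        self.pixel_id = int(self.pixel_id)

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class LandmarkSet:
    """Paired landmark coordinates (um) in the source and target frames."""

    source_xy: np.ndarray
    target_xy: np.ndarray

    def __post_init__(self) -> None:
        self.source_xy = _as_float_array(self.source_xy, "source_xy", 2)
        self.target_xy = _as_float_array(self.target_xy, "target_xy", 2)
        k = self.source_xy.shape[0]
        if self.source_xy.shape[1] != 2 or self.target_xy.shape != (k, 2):
            raise ValidationError("landmark arrays must be k x 2 and matched")
        if k < 3:
            raise ValidationError("insufficient landmarks: need at least 3 pairs")
        if _collinear(self.source_xy):
            raise ValidationError("degenerate landmarks: source points are collinear")

    @property
    def k(self) -> int:
        return self.source_xy.shape[0]


def _collinear(points: np.ndarray, tol: float = 1e-9) -> bool:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    scale = max(s[0], 1.0)
    return s[-1] <= tol * scale


# ---------------------------------------------------------------------------
# wide CSV
# ---------------------------------------------------------------------------

def _parse_float(token: str, row: int, col: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(
            f"non-numeric cell {token!r} at row {row}, column {col}"
        ) from None


def _read_wide_csv(path: Path, modality: str) -> SpectralMap:
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split(",")
    if len(header) < 3:
        raise ParseError(f"{path}: header must contain x,y and at least one channel")
    axis = np.array(
        [_parse_float(tok, 1, j + 3) for j, tok in enumerate(header[2:])]
    )
    if len(lines) < 2:
        raise ParseError(f"{path}: no pixel rows")
    n_ch = axis.size
    coords = np.empty((len(lines) - 1, 2))
    intens = np.empty((len(lines) - 1, n_ch))
    for i, ln in enumerate(lines[1:], start=2):
        toks = ln.split(",")
        if len(toks) != n_ch + 2:
            raise ParseError(
                f"{path}: row {i} has {len(toks)} fields, expected {n_ch + 2}"
            )
        coords[i - 2, 0] = _parse_float(toks[0], i, 1)
        coords[i - 2, 1] = _parse_float(toks[1], i, 2)
        for j, tok in enumerate(toks[2:]):
            intens[i - 2, j] = _parse_float(tok, i, j + 3)
    order = np.argsort(axis, kind="stable")
    return SpectralMap(intens[:, order], axis[order], coords, modality)


def _write_wide_csv(m: SpectralMap, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("x,y," + ",".join(f"{v:.12g}" for v in m.axis) + "\n")
        for xy, row in zip(m.coords, m.intensities):
            fh.write(
                f"{xy[0]:.12g},{xy[1]:.12g},"
                + ",".join(f"{v:.12g}" for v in row)
                + "\n"
            )


# ---------------------------------------------------------------------------
# imzML (minimal)
# ---------------------------------------------------------------------------

_NS = "http://psi.hupo.org/ms/mzml"
_DTYPES = {
    "MS:1000521": np.dtype("<f4"),  # 32-bit float
    "MS:1000523": np.dtype("<f8"),  # 64-bit float
}
_IMS_CONTINUOUS = "IMS:1000030"
_IMS_PROCESSED = "IMS:1000031"


def _cv(elem: ET.Element, accession: str):
    for p in elem.iter(f"{{{_NS}}}cvParam"):
        if p.get("accession") == accession:
            return p
    return None


def _read_ibd_array(ibd: bytes, offset: int, length: int, dtype: np.dtype) -> np.ndarray:
    end = offset + length * dtype.itemsize
    return np.frombuffer(ibd[offset:end], dtype=dtype).astype(float)


def _parse_imzml(path: Path):
    """Return (mode, pixel size, list of (x_idx, y_idx, mz array, int array))."""
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ParseError(f"{path}: invalid imzML XML ({exc})") from None
    root = tree.getroot()
    mode = "continuous" if _cv(root, _IMS_CONTINUOUS) is not None else None
    if mode is None and _cv(root, _IMS_PROCESSED) is not None:
        mode = "processed"
    if mode is None:
        raise ParseError(f"{path}: neither continuous nor processed mode declared")

    px = py = 1.0
    scan = root.find(f".//{{{_NS}}}scanSettingsList")
    if scan is not None:
        p = _cv(scan, "IMS:1000046")
        if p is not None:
            px = float(p.get("value"))
        p = _cv(scan, "IMS:1000047")
        if p is not None:
            py = float(p.get("value"))

    ibd_path = path.with_suffix(".ibd")
    if not ibd_path.exists():
        raise ParseError(f"{path}: paired .ibd file not found")
    ibd = ibd_path.read_bytes()

    # dtype per referenceable param group (mzArray / intensityArray)
    group_dtype: dict[str, np.dtype] = {}
    for grp in root.iter(f"{{{_NS}}}referenceableParamGroup"):
        for acc, dt in _DTYPES.items():
            if _cv(grp, acc) is not None:
                group_dtype[grp.get("id")] = dt

    spectra = []
    for spec in root.iter(f"{{{_NS}}}spectrum"):
        xp = _cv(spec, "IMS:1000050")
        yp = _cv(spec, "IMS:1000051")
        if xp is None or yp is None:
            raise ParseError(f"{path}: spectrum without x/y position")
        arrays = {}
        for bda in spec.iter(f"{{{_NS}}}binaryDataArray"):
            ref = bda.find(f"{{{_NS}}}referenceableParamGroupRef")
            gid = ref.get("ref") if ref is not None else None
            dt = group_dtype.get(gid)
            for acc, cand in _DTYPES.items():
                if _cv(bda, acc) is not None:
                    dt = cand
            if dt is None:
                dt = np.dtype("<f8")
            offset = int(_cv(bda, "IMS:1000102").get("value"))
            length = int(_cv(bda, "IMS:1000103").get("value"))
            kind = "mz" if (gid and "mz" in gid.lower()) else "intensity"
            if _cv(bda, "MS:1000514") is not None:
                kind = "mz"
            elif _cv(bda, "MS:1000515") is not None:
                kind = "intensity"
            arrays[kind] = _read_ibd_array(ibd, offset, length, dt)
        if "mz" not in arrays or "intensity" not in arrays:
            raise ParseError(f"{path}: spectrum missing m/z or intensity array")
        spectra.append(
            (int(xp.get("value")), int(yp.get("value")), arrays["mz"], arrays["intensity"])
        )
    if not spectra:
        raise ParseError(f"{path}: no spectra found")
    return mode, (px, py), spectra


def _read_imzml(path: Path, modality: str) -> SpectralMap:
    mode, (px, py), spectra = _parse_imzml(path)
    axis = spectra[0][2]
    coords = np.empty((len(spectra), 2))
    intens = np.empty((len(spectra), axis.size))
    for i, (ix, iy, mz, inten) in enumerate(spectra):
        if mode == "continuous":
            if mz.size != axis.size or not np.allclose(mz, axis):
                raise ParseError(f"{path}: continuous mode but axes differ across pixels")
        else:
            if mz.size != axis.size or not np.array_equal(mz, axis):
                raise ParseError(
                    f"{path}: processed mode with per-pixel axes cannot form a "
                    "SpectralMap; use read_imzml_peaklists"
                )
        coords[i] = ((ix - 1) * px, (iy - 1) * py)
        intens[i] = inten
    order = np.argsort(axis, kind="stable")
    return SpectralMap(intens[:, order], axis[order], coords, modality)


def read_imzml_peaklists(path) -> list[PeakList]:
    """Read a processed-mode imzML file as one :class:`PeakList` per pixel."""
    _, _, spectra = _parse_imzml(Path(path))
    lists = []
    for i, (_, _, mz, inten) in enumerate(spectra):
        order = np.argsort(mz, kind="stable")
        lists.append(PeakList(mz[order], inten[order], pixel_id=i))
    return lists


def _infer_grid_index(values: np.ndarray):
    """Map real coordinates to 1-based integer grid indices and a pitch."""
    uniq = np.unique(values)
    if uniq.size == 1:
        return np.ones(values.size, dtype=int), 1.0
    pitch = float(np.min(np.diff(uniq)))
    idx = np.rint((values - uniq[0]) / pitch).astype(int) + 1
    if not np.allclose((idx - 1) * pitch + uniq[0], values, atol=1e-6 * pitch):
        raise ValidationError(
            "coordinates do not lie on a regular grid; imzML export needs one"
        )
    return idx, pitch


def _write_imzml(m: SpectralMap, path: Path) -> None:
    ix, px = _infer_grid_index(m.coords[:, 0])
    iy, py = _infer_grid_index(m.coords[:, 1])
    uid = uuid.uuid4()
    ibd_path = path.with_suffix(".ibd")
    dtype = np.dtype("<f8")

    with open(ibd_path, "wb") as fh:
        fh.write(uid.bytes)
        mz_offset = fh.tell()
        fh.write(m.axis.astype(dtype).tobytes())
        int_offsets = []
        for row in m.intensities:
            int_offsets.append(fh.tell())
            fh.write(row.astype(dtype).tobytes())

    def cvparam(parent, cvref, acc, name, value=""):
        ET.SubElement(
            parent,
            "cvParam",
            cvRef=cvref,
            accession=acc,
            name=name,
            value=str(value),
        )

    root = ET.Element("mzML", xmlns=_NS, version="1.1")
    cvlist = ET.SubElement(root, "cvList", count="2")
    ET.SubElement(cvlist, "cv", id="MS", fullName="Proteomics Standards Initiative Mass Spectrometry Ontology")
    ET.SubElement(cvlist, "cv", id="IMS", fullName="Imaging MS Ontology")
    fdesc = ET.SubElement(root, "fileDescription")
    fcontent = ET.SubElement(fdesc, "fileContent")
    cvparam(fcontent, "IMS", _IMS_CONTINUOUS, "continuous")
    cvparam(fcontent, "IMS", "IMS:1000080", "universally unique identifier", f"{{{uid}}}")

    rpgl = ET.SubElement(root, "referenceableParamGroupList", count="2")
    g = ET.SubElement(rpgl, "referenceableParamGroup", id="mzArray")
    cvparam(g, "MS", "MS:1000523", "64-bit float")
    cvparam(g, "MS", "MS:1000514", "m/z array")
    cvparam(g, "IMS", "IMS:1000101", "external data", "true")
    g = ET.SubElement(rpgl, "referenceableParamGroup", id="intensityArray")
    cvparam(g, "MS", "MS:1000523", "64-bit float")
    cvparam(g, "MS", "MS:1000515", "intensity array")
    cvparam(g, "IMS", "IMS:1000101", "external data", "true")

    ssl = ET.SubElement(root, "scanSettingsList", count="1")
    ss = ET.SubElement(ssl, "scanSettings", id="scan1")
    cvparam(ss, "IMS", "IMS:1000042", "max count of pixels x", int(ix.max()))
    cvparam(ss, "IMS", "IMS:1000043", "max count of pixels y", int(iy.max()))
    cvparam(ss, "IMS", "IMS:1000046", "pixel size x", px)
    cvparam(ss, "IMS", "IMS:1000047", "pixel size y", py)

    run = ET.SubElement(root, "run", id="run1")
    sl = ET.SubElement(run, "spectrumList", count=str(m.n_pixels))
    for i in range(m.n_pixels):
        spec = ET.SubElement(sl, "spectrum", id=f"spectrum={i}", index=str(i), defaultArrayLength=str(m.n_channels))
        scanlist = ET.SubElement(spec, "scanList", count="1")
        scan = ET.SubElement(scanlist, "scan")
        cvparam(scan, "IMS", "IMS:1000050", "position x", int(ix[i]))
        cvparam(scan, "IMS", "IMS:1000051", "position y", int(iy[i]))
        bdal = ET.SubElement(spec, "binaryDataArrayList", count="2")
        for gid, offset, length in (
            ("mzArray", mz_offset, m.n_channels),
            ("intensityArray", int_offsets[i], m.n_channels),
        ):
            bda = ET.SubElement(bdal, "binaryDataArray", encodedLength="0")
            ET.SubElement(bda, "referenceableParamGroupRef", ref=gid)
            cvparam(bda, "IMS", "IMS:1000102", "external offset", offset)
            cvparam(bda, "IMS", "IMS:1000103", "external array length", length)
            cvparam(
                bda,
                "IMS",
                "IMS:1000104",
                "external encoded length",
                length * dtype.itemsize,
            )
            ET.SubElement(bda, "binary")
    ET.indent(root)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def read_spectral_map(path, format: str = "wide_csv", modality: str = "raman") -> SpectralMap:
    """Read a spectral map, sorting the channel axis ascending if needed."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "wide_csv":
        return _read_wide_csv(path, modality)
    if format == "imzml":
        return _read_imzml(path, modality)
    raise ParameterError(f"unknown format {format!r}; expected 'wide_csv' or 'imzml'")


def write_spectral_map(m: SpectralMap, path, format: str = "wide_csv") -> None:
    path = Path(path)
    if format == "wide_csv":
        _write_wide_csv(m, path)
    elif format == "imzml":
        _write_imzml(m, path)
    else:
        raise ParameterError(f"unknown format {format!r}; expected 'wide_csv' or 'imzml'")


def read_landmarks(path) -> LandmarkSet:
    """Read a 4-column CSV (x_src, y_src, x_tgt, y_tgt) of paired landmarks."""
    path = Path(path)
    text = path.read_text()
    rows = []
    for i, ln in enumerate(text.splitlines(), start=1):
        if not ln.strip():
            continue
        toks = ln.split(",")
        if i == 1 and any(not _is_number(t) for t in toks):
            continue  # optional header row
        if len(toks) != 4:
            raise ParseError(f"{path}: row {i} has {len(toks)} fields, expected 4")
        rows.append([_parse_float(t, i, j + 1) for j, t in enumerate(toks)])
    if len(rows) < 3:
        raise ValidationError("insufficient landmarks: need at least 3 pairs")
    arr = np.array(rows)
    return LandmarkSet(arr[:, :2], arr[:, 2:])


def write_landmarks(lm: LandmarkSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("x_src,y_src,x_tgt,y_tgt\n")
        for s, t in zip(lm.source_xy, lm.target_xy):
            fh.write(f"{s[0]:.12g},{s[1]:.12g},{t[0]:.12g},{t[1]:.12g}\n")


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False
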