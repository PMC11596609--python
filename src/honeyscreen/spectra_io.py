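"""Reading and writing centroided LC-MS runs as mzML.

A run is a time-ordered list of centroid spectra: MS1 full scans over
100-1500 Da plus, optionally, MS2 scans acquired with the variable
data-independent acquisition (vDIA) scheme, in which all ions inside a
series of fixed precursor isolation windows are fragmented together.
The six canonical vDIA windows tile the full-scan mass range without
gaps; each MS2 scan is annotated with the canonical window nearest to
its recorded isolation window (1 Da midpoint tolerance, to absorb the
small numeric jitter vendor converters introduce).

Both directions are implemented on the standard-library XML tools: the
reader streams ``spectrum`` elements (plain or ``indexedmzML``,
32/64-bit float arrays, zlib-compressed or uncompressed) and the writer
emits minimal conforming centroid mzML (64-bit float, uncompressed).
Retention times are seconds everywhere in this package; minute-valued
mzML scan times are converted on read.
Only centroided input is accepted - profile spectra raise
:class:`ProfileModeError`, since peak picking of profile data is a
vendor-conversion concern, not part of this pipeline.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np

__all__ = [
    "VdiaWindow",
    "CANONICAL_WINDOWS",
    "CentroidSpectrum",
    "LcmsRun",
    "MODES",
    "FULL_SCAN_RANGE",
    "match_window",
    "read_run",
    "write_run",
    "validate_run",
    "read_metadata",
    "ProfileModeError",
    "WindowError",
    "MzmlParseError",
]

#: Chromatography / ionization modes used in the study design.
MODES = ("HILIC_neg", "RP_pos")

#: MS1 full-scan acquisition range, Da.
FULL_SCAN_RANGE = (100.0, 1500.0)


class ProfileModeError(ValueError):
    """Input contains profile-mode spectra; only centroided data is supported."""


class WindowError(ValueError):
    """An MS2 isolation window matches no canonical vDIA window."""


class MzmlParseError(ValueError):
    """The file is not parseable as mzML."""


@dataclass(frozen=True)
class VdiaWindow:
    """One vDIA precursor isolation window and its fragment detection range (Da)."""

    precursor_low: float
    precursor_high: float
    fragment_low: float
    fragment_high: float

    def __post_init__(self) -> None:
        if not (self.precursor_low < self.precursor_high):
            raise ValueError("precursor_low must be < precursor_high")
        if not (self.fragment_low < self.fragment_high):
            raise ValueError("fragment_low must be < fragment_high")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.precursor_low + self.precursor_high)


#: The six canonical vDIA windows: precursor ranges tile 100-1500 Da.
CANONICAL_WINDOWS: tuple[VdiaWindow, ...] = (
    VdiaWindow(100.0, 200.0, 50.0, 225.0),
    VdiaWindow(200.0, 300.0, 50.0, 330.0),
    VdiaWindow(300.0, 400.0, 50.0, 430.0),
    VdiaWindow(400.0, 500.0, 50.0, 535.0),
    VdiaWindow(500.0, 1000.0, 69.0, 1045.0),
    VdiaWindow(1000.0, 1500.0, 104.0, 1555.0),
)


def match_window(precursor_low: float, precursor_high: float, tol: float = 1.0) -> VdiaWindow:
    """Map a recorded isolation window to the nearest canonical vDIA window.

    Matching is by window midpoint with a ``tol`` Da tolerance.

    Raises
    ------
    WindowError
        If no canonical window midpoint lies within ``tol`` Da.
    """
    mid = 0.5 * (precursor_low + precursor_high)
    best = min(CANONICAL_WINDOWS, key=lambda w: abs(w.midpoint - mid))
    if abs(best.midpoint - mid) > tol:
        raise WindowError(
            f"isolation window {precursor_low:g}-{precursor_high:g} Da matches no "
            f"canonical vDIA window within {tol:g} Da"
        )
    return best


@dataclass
class CentroidSpectrum:
    """A single centroided scan.

    ``window`` is present exactly when ``ms_level == 2``; m/z values are
    strictly increasing and intensities nonnegative.
    """

    rt: float  # seconds
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    window: VdiaWindow | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")
        if self.ms_level == 1 and self.window is not None:
            raise ValueError("MS1 scans carry no isolation window")
        if self.ms_level == 2 and self.window is None:
            raise ValueError("MS2 scans require a vDIA window")


@dataclass
class LcmsRun:
    """One LC-MS run: identity, acquisition mode, and its time-ordered scans."""

    sample_id: str
    mode: str
    scans: list[CentroidSpectrum] = field(default_factory=list)
    device_id: str = ""

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        rts = [s.rt for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            self.scans = sorted(self.scans, key=lambda s: s.rt)

    def scans_at(self, ms_level: int, window: VdiaWindow | None = None) -> list[CentroidSpectrum]:
        """Scans of a given MS level (and, for MS2, a given vDIA window)."""
        if ms_level == 1:
            return [s for s in self.scans if s.ms_level == 1]
        return [s for s in self.scans if s.ms_level == 2 and s.window == window]


def validate_run(run: LcmsRun) -> None:
    """Check a run against the acquisition scheme.

    MS1 centroids must lie inside the full-scan range and every MS2 scan
    must carry one of the six canonical windows.
    """
    lo, hi = FULL_SCAN_RANGE
    for s in run.scans:
        if s.ms_level == 1:
            if s.mz.size and (s.mz[0] < lo or s.mz[-1] > hi):
                raise ValueError(
                    f"MS1 centroids outside the {lo:g}-{hi:g} Da full-scan range "
                    f"in run {run.sample_id!r} at RT {s.rt:g} s"
                )
        elif s.window not in CANONICAL_WINDOWS:
            raise WindowError(f"non-canonical MS2 window in run {run.sample_id!r}")


# ---------------------------------------------------------------------------
# mzML reading
# ---------------------------------------------------------------------------

_NS = "http://psi.hupo.org/ms/mzml"

# PSI-MS controlled-vocabulary accessions used on read.
_ACC_MS_LEVEL = "MS:1000511"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_ISO_TARGET = "MS:1000827"
_ACC_ISO_LOWER = "MS:1000828"
_ACC_ISO_UPPER = "MS:1000829"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MINUTE = "UO:0000031"


def _local(tag: str) -> str:
    return tag.rpartition("}")[2]


def _cv_index(element: ET.Element) -> dict[str, str]:
    """accession -> value for all cvParams directly under ``element``."""
    return {
        child.get("accession", ""): child.get("value", "")
        for child in element
        if _local(child.tag) == "cvParam"
    }


def _iter_named(element: ET.Element, name: str):
    for child in element.iter():
        if _local(child.tag) == name:
            yield child


def _first_named(element: ET.Element, name: str) -> ET.Element | None:
    return next(_iter_named(element, name), None)


def _decode_binary_array(array_el: ET.Element) -> np.ndarray:
    params = _cv_index(array_el)
    binary = _first_named(array_el, "binary")
    text = (binary.text or "") if binary is not None else ""
    raw = base64.b64decode(text)
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_F32 in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _parse_spectrum(spec_el: ET.Element, source: str) -> CentroidSpectrum:
    params = _cv_index(spec_el)
    if _ACC_PROFILE in params:
        raise ProfileModeError(
            f"{source}: profile-mode spectrum {spec_el.get('id')!r}; "
            "centroid the data before import"
        )
    level = int(params.get(_ACC_MS_LEVEL, "1"))

    rt = 0.0
    scan_el = _first_named(spec_el, "scan")
    if scan_el is not None:
        for cv in scan_el:
            if _local(cv.tag) == "cvParam" and cv.get("accession") == _ACC_SCAN_START:
                rt = float(cv.get("value", "0"))
                if cv.get("unitAccession") == _ACC_MINUTE or "min" in cv.get("unitName", ""):
                    rt *= 60.0

    window = None
    if level >= 2:
        iso_el = _first_named(spec_el, "isolationWindow")
        if iso_el is None:
            raise MzmlParseError(f"{source}: MS{level} spectrum without isolation window")
        iso = _cv_index(iso_el)
        target = float(iso[_ACC_ISO_TARGET])
        lo = target - float(iso[_ACC_ISO_LOWER])
        hi = target + float(iso[_ACC_ISO_UPPER])
        window = match_window(lo, hi)

    mz = intensity = None
    for arr_el in _iter_named(spec_el, "binaryDataArray"):
        arr_params = _cv_index(arr_el)
        if _ACC_MZ_ARRAY in arr_params:
            mz = _decode_binary_array(arr_el)
        elif _ACC_INT_ARRAY in arr_params:
            intensity = _decode_binary_array(arr_el)
    if mz is None or intensity is None:
        raise MzmlParseError(f"{source}: spectrum without m/z or intensity array")
    return CentroidSpectrum(rt=rt, ms_level=level, mz=mz, intensity=intensity, window=window)


def read_run(
    path: str | Path,
    mode: str,
    sample_id: str | None = None,
    device_id: str | None = None,
) -> LcmsRun:
    """Read an mzML file of centroided spectra into an :class:`LcmsRun`.

    MS2 scans are annotated with the canonical vDIA window nearest their
    isolation window (1 Da midpoint tolerance). Scans are returned sorted
    by retention time, in seconds.

    ``sample_id`` and ``device_id`` default to the values stored in the
    file's run-level userParams (written by :func:`write_run`), falling
    back to the file stem and empty string.
    """
    path = Path(path)
    scans: list[CentroidSpectrum] = []
    meta: dict[str, str] = {}
    saw_mzml = False
    try:
        for event, el in ET.iterparse(path, events=("end",)):
            tag = _local(el.tag)
            if tag == "spectrum":
                scans.append(_parse_spectrum(el, path.name))
                el.clear()
            elif tag == "run":
                for up in el:
                    if _local(up.tag) == "userParam":
                        meta[up.get("name", "")] = up.get("value", "")
            elif tag == "mzML":
                saw_mzml = True
    except ET.ParseError as exc:
        raise MzmlParseError(f"cannot parse {path} as mzML: {exc}") from exc
    if not saw_mzml:
        raise MzmlParseError(f"{path} contains no mzML document")
    if sample_id is None:
        sample_id = meta.get("sample_id") or path.stem
    if device_id is None:
        device_id = meta.get("device_id", "")
    scans.sort(key=lambda s: s.rt)
    return LcmsRun(sample_id=sample_id, mode=mode, scans=scans, device_id=device_id)


# ---------------------------------------------------------------------------
# mzML writing
# ---------------------------------------------------------------------------

def _b64(values: np.ndarray) -> str:
    return base64.b64encode(
        struct.pack(f"<{values.size}d", *np.asarray(values, dtype=np.float64))
    ).decode("ascii")


def _cv(parent: ET.Element, accession: str, name: str, value: str = "", **extra: str) -> None:
    ET.SubElement(
        parent, "cvParam", cvRef="MS", accession=accession, name=name, value=value, **extra
    )


_SECOND_UNIT = dict(unitCvRef="UO", unitAccession="UO:0000010", unitName="second")
_MZ_UNIT = dict(unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z")


def _binary_array(parent: ET.Element, data: np.ndarray, accession: str, name: str, unit: dict) -> None:
    encoded = _b64(data)
    arr = ET.SubElement(parent, "binaryDataArray", encodedLength=str(len(encoded)))
    _cv(arr, "MS:1000523", "64-bit float")
    _cv(arr, "MS:1000576", "no compression")
    _cv(arr, accession, name, **unit)
    ET.SubElement(arr, "binary").text = encoded


def write_run(run: LcmsRun, path: str | Path) -> Path:
    """Write a run as standard-conforming centroid mzML.

    ``read_run(write_run(run)) == run`` up to float64 round-trip; the
    sample id, mode and device id are stored as run-level userParams.
    """
    path = Path(path)
    root = ET.Element("mzML", xmlns=_NS, version="1.1.0")
    cvlist = ET.SubElement(root, "cvList", count="2")
    ET.SubElement(cvlist, "cv", id="MS", fullName="Proteomics Standards Initiative Mass Spectrometry Ontology", URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo")
    ET.SubElement(cvlist, "cv", id="UO", fullName="Unit Ontology", URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo")
    fdesc = ET.SubElement(root, "fileDescription")
    fcontent = ET.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000579", "MS1 spectrum")
    _cv(fcontent, "MS:1000127", "centroid spectrum")
    soft_list = ET.SubElement(root, "softwareList", count="1")
    ET.SubElement(soft_list, "software", id="honeyscreen", version="0.1.0")
    icl = ET.SubElement(root, "instrumentConfigurationList", count="1")
    ic = ET.SubElement(icl, "instrumentConfiguration", id="IC1")
    _cv(ic, "MS:1000031", "instrument model")
    dpl = ET.SubElement(root, "dataProcessingList", count="1")
    dp = ET.SubElement(dpl, "dataProcessing", id="DP1")
    pm = ET.SubElement(dp, "processingMethod", order="1", softwareRef="honeyscreen")
    _cv(pm, "MS:1000544", "Conversion to mzML")

    run_el = ET.SubElement(
        root, "run", id=run.sample_id or "run", defaultInstrumentConfigurationRef="IC1"
    )
    for name, value in (
        ("sample_id", run.sample_id),
        ("mode", run.mode),
        ("device_id", run.device_id),
    ):
        ET.SubElement(run_el, "userParam", name=name, value=value)
    spec_list = ET.SubElement(
        run_el, "spectrumList", count=str(len(run.scans)), defaultDataProcessingRef="DP1"
    )
    for i, scan in enumerate(run.scans):
        spec = ET.SubElement(
            spec_list,
            "spectrum",
            index=str(i),
            id=f"scan={i + 1}",
            defaultArrayLength=str(scan.mz.size),
        )
        _cv(spec, "MS:1000511", "ms level", str(scan.ms_level))
        _cv(spec, "MS:1000127", "centroid spectrum")
        kind = ("MS:1000579", "MS1 spectrum") if scan.ms_level == 1 else ("MS:1000580", "MSn spectrum")
        _cv(spec, *kind)
        scan_list = ET.SubElement(spec, "scanList", count="1")
        _cv(scan_list, "MS:1000795", "no combination")
        scan_el = ET.SubElement(scan_list, "scan")
        _cv(scan_el, "MS:1000016", "scan start time", repr(scan.rt), **_SECOND_UNIT)
        if scan.ms_level == 2:
            w = scan.window
            plist = ET.SubElement(spec, "precursorList", count="1")
            prec = ET.SubElement(plist, "precursor")
            iso = ET.SubElement(prec, "isolationWindow")
            half = 0.5 * (w.precursor_high - w.precursor_low)
            _cv(iso, "MS:1000827", "isolation window target m/z", repr(w.midpoint), **_MZ_UNIT)
            _cv(iso, "MS:1000828", "isolation window lower offset", repr(half), **_MZ_UNIT)
            _cv(iso, "MS:1000829", "isolation window upper offset", repr(half), **_MZ_UNIT)
            act = ET.SubElement(prec, "activation")
            _cv(act, "MS:1000422", "beam-type collision-induced dissociation")
        arrays = ET.SubElement(spec, "binaryDataArrayList", count="2")
        _binary_array(arrays, scan.mz, "MS:1000514", "m/z array", _MZ_UNIT)
        _binary_array(
            arrays,
            scan.intensity,
            "MS:1000515",
            "intensity array",
            dict(unitCvRef="MS", unitAccession="MS:1000131", unitName="number of detector counts"),
        )
    ET.indent(root)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Sample metadata table
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ("sample_id", "honey_id", "syrup", "proportion_pct", "device_id", "mode", "path")


def read_metadata(path: str | Path):
    """Read the sample-metadata CSV and validate its schema.

    Columns: sample_id, honey_id, syrup, proportion_pct, device_id, mode,
    path. ``syrup == 'none'`` must coincide with ``proportion_pct == 0``.
    """
    import pandas as pd

    df = pd.read_csv(path, dtype={"sample_id": str, "honey_id": str, "device_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table missing columns: {missing}")
    bad_mode = set(df["mode"]) - set(MODES)
    if bad_mode:
        raise ValueError(f"unknown modes in metadata: {sorted(bad_mode)}")
    pure = df["syrup"].eq("none")
    if not (pure == df["proportion_pct"].eq(0)).all():
        raise ValueError("syrup == 'none' must coincide with proportion_pct == 0")
    return df
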