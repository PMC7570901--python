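"""Raw-run model and spectral processing.

A :class:`Run` is an ordered list of MS1/MS2 scans with retention times,
peak arrays, precursor and fragmentation-mode metadata (HCD collision
energy or UVPD reaction time).  Runs are read from and written to mzML
1.1 (indexed or plain; uncompressed or zlib, 32/64-bit float arrays) so
external tools can inspect synthetic fixtures.

Processing steps: profile-mode centroiding (local-maximum regions reduced
to an intensity-weighted m/z and the apex intensity), extracted ion
chromatograms with apex and trapezoidal area, and selection of the top-n
highest-master-intensity MS2 scans near the chromatographic apex per
fragmentation mode.
"""

from __future__ import annotations

import base64
import logging
import xml.etree.ElementTree as ET
import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from lxml import etree

__all__ = [
    "FragMode",
    "Spectrum",
    "Run",
    "RunFormatError",
    "read_run",
    "write_mzml",
    "centroid_spectrum",
    "XIC",
    "xic",
    "select_top_ms2",
]

logger = logging.getLogger(__name__)


class RunFormatError(ValueError):
    """Malformed run data (mzML structure or scan-level invariants)."""


@dataclass(frozen=True)
class FragMode:
    """Fragmentation mode label: HCD with a collision energy (arbitrary
    units) or UVPD with a reaction time in milliseconds."""

    technique: str  # "HCD", "UVPD" or "unknown"
    energy: float = 0.0

    def __str__(self) -> str:
        if self.technique == "HCD":
            return f"HCD@{self.energy:g}CE"
        if self.technique == "UVPD":
            return f"UVPD@{self.energy:g}ms"
        return "unknown"


@dataclass
class Spectrum:
    """One scan: peak arrays plus acquisition metadata."""

    scan_number: int
    ms_level: int
    rt: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray
    is_profile: bool = False
    precursor_mz: Optional[float] = None
    frag_mode: Optional[FragMode] = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise RunFormatError(
                f"scan {self.scan_number}: m/z and intensity arrays differ in length"
            )
        if self.mz.size > 1 and np.any(np.diff(self.mz) < 0):
            raise RunFormatError(f"scan {self.scan_number}: m/z array not ascending")
        if self.ms_level >= 2 and self.precursor_mz is None:
            raise RunFormatError(
                f"scan {self.scan_number}: MS2 scan without precursor m/z"
            )


@dataclass
class Run:
    """An ordered LC-MS run."""

    scans: List[Spectrum]
    source: str = ""

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.scans]
        if any(b < a - 1e-9 for a, b in zip(rts, rts[1:])):
            raise RunFormatError("retention times not non-decreasing with scan order")

    def ms_scans(self, level: int) -> List[Spectrum]:
        return [s for s in self.scans if s.ms_level == level]

    def frag_modes(self) -> List[FragMode]:
        seen: Dict[FragMode, None] = {}
        for s in self.scans:
            if s.ms_level >= 2 and s.frag_mode is not None:
                seen.setdefault(s.frag_mode)
        return list(seen)


# ---------------------------------------------------------------------------
# mzML I/O

_NS = "http://psi.hupo.org/ms/mzml"


def _parse_activation(activation: dict, scan_number: int) -> FragMode:
    if not activation:
        logger.warning("scan %d: missing activation metadata", scan_number)
        return FragMode("unknown")
    if "beam-type collision-induced dissociation" in activation:
        ce = float(activation.get("collision energy", 0.0))
        return FragMode("HCD", ce)
    if "ultraviolet photodissociation" in activation or "reaction time" in activation:
        rt_ms = float(activation.get("reaction time", 0.0))
        return FragMode("UVPD", rt_ms)
    logger.warning("scan %d: unrecognized activation %s", scan_number, list(activation))
    return FragMode("unknown")


def _params(el: "etree._Element") -> Dict[str, str]:
    """cvParam/userParam children of an element as a name -> value map."""
    out: Dict[str, str] = {}
    for child in el:
        tag = etree.QName(child).localname
        if tag in ("cvParam", "userParam"):
            out[child.get("name", "")] = child.get("value", "")
    return out


def _decode_array(bda: "etree._Element", n_points: int) -> Tuple[str, np.ndarray]:
    params = _params(bda)
    binary = bda.find(f"{{{_NS}}}binary")
    text = binary.text if binary is not None and binary.text else ""
    raw = base64.b64decode(text)
    if "zlib compression" in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if "32-bit float" in params else "<f8"
    arr = np.frombuffer(raw, dtype=dtype).astype(np.float64)
    name = "m/z array" if "m/z array" in params else (
        "intensity array" if "intensity array" in params else "other"
    )
    if n_points and arr.size != n_points:
        raise RunFormatError(f"binary array length {arr.size} != declared {n_points}")
    return name, arr


def read_run(path: str) -> Run:
    """Read an mzML 1.1 file (indexed or plain) into a :class:`Run`.

    Retention times are converted to minutes; fragmentation metadata is
    parsed from the activation element (HCD collision energy, UVPD
    reaction time; missing metadata yields an "unknown" mode with a
    warning).  An MS2 scan without a selected-ion m/z raises
    :class:`RunFormatError` naming the scan.
    """
    try:
        tree = etree.parse(str(path))
    except (OSError, etree.XMLSyntaxError) as exc:
        raise RunFormatError(f"cannot read mzML file {path}: {exc}") from exc
    root = tree.getroot()
    spectra = root.findall(f".//{{{_NS}}}spectrum")
    scans: List[Spectrum] = []
    for i, el in enumerate(spectra):
        sid = el.get("id", f"scan={i + 1}")
        try:
            scan_number = int(str(sid).rsplit("=", 1)[-1])
        except ValueError:
            scan_number = i + 1
        params = _params(el)
        ms_level = int(float(params.get("ms level", 1)))
        is_profile = "profile spectrum" in params
        rt = 0.0
        scan_el = el.find(f"{{{_NS}}}scanList/{{{_NS}}}scan")
        if scan_el is not None:
            for child in scan_el:
                if child.get("accession") == "MS:1000016" or child.get("name") == "scan start time":
                    rt = float(child.get("value", 0.0))
                    if str(child.get("unitName", "minute")).startswith("second"):
                        rt /= 60.0
        precursor_mz = None
        frag_mode = None
        if ms_level >= 2:
            prec = el.find(f"{{{_NS}}}precursorList/{{{_NS}}}precursor")
            if prec is not None:
                sion = prec.find(f"{{{_NS}}}selectedIonList/{{{_NS}}}selectedIon")
                if sion is not None:
                    val = _params(sion).get("selected ion m/z")
                    precursor_mz = float(val) if val is not None else None
                act = prec.find(f"{{{_NS}}}activation")
                frag_mode = _parse_activation(
                    _params(act) if act is not None else {}, scan_number
                )
            if precursor_mz is None:
                raise RunFormatError(f"scan {scan_number}: MS2 scan without precursor")
        n_points = int(el.get("defaultArrayLength", 0))
        mz = intensity = np.empty(0)
        for bda in el.findall(f"{{{_NS}}}binaryDataArrayList/{{{_NS}}}binaryDataArray"):
            name, arr = _decode_array(bda, n_points)
            if name == "m/z array":
                mz = arr
            elif name == "intensity array":
                intensity = arr
        scans.append(
            Spectrum(
                scan_number=scan_number,
                ms_level=ms_level,
                rt=rt,
                mz=mz,
                intensity=intensity,
                is_profile=is_profile,
                precursor_mz=precursor_mz,
                frag_mode=frag_mode,
            )
        )
    return Run(scans=scans, source=str(path))


def _cv(parent: ET.Element, accession: str, name: str, value: str = "", **attrs: str) -> None:
    ET.SubElement(
        parent, "cvParam", cvRef="MS", accession=accession, name=name, value=value, **attrs
    )


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode("ascii")


def write_mzml(run: Run, path: str) -> None:
    """Write a run as plain mzML 1.1 (64-bit float arrays, no compression)."""
    root = ET.Element("mzML", xmlns=_NS, version="1.1.0")
    cvlist = ET.SubElement(root, "cvList", count="1")
    ET.SubElement(
        cvlist, "cv", id="MS", fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    fdesc = ET.SubElement(root, "fileDescription")
    fcontent = ET.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000580", "MSn spectrum")
    sw_list = ET.SubElement(root, "softwareList", count="1")
    ET.SubElement(sw_list, "software", id="fragmode", version="0.1.0")
    icl = ET.SubElement(root, "instrumentConfigurationList", count="1")
    ET.SubElement(icl, "instrumentConfiguration", id="IC1")
    dpl = ET.SubElement(root, "dataProcessingList", count="1")
    dp = ET.SubElement(dpl, "dataProcessing", id="DP1")
    pm = ET.SubElement(dp, "processingMethod", order="1", softwareRef="fragmode")
    _cv(pm, "MS:1000544", "Conversion to mzML")
    run_el = ET.SubElement(root, "run", id="run1", defaultInstrumentConfigurationRef="IC1")
    slist = ET.SubElement(
        run_el, "spectrumList", count=str(len(run.scans)), defaultDataProcessingRef="DP1"
    )
    for idx, sp in enumerate(run.scans):
        el = ET.SubElement(
            slist, "spectrum", index=str(idx), id=f"scan={sp.scan_number}",
            defaultArrayLength=str(sp.mz.size),
        )
        _cv(el, "MS:1000511", "ms level", str(sp.ms_level))
        if sp.is_profile:
            _cv(el, "MS:1000128", "profile spectrum")
        else:
            _cv(el, "MS:1000127", "centroid spectrum")
        scan_list = ET.SubElement(el, "scanList", count="1")
        _cv(scan_list, "MS:1000795", "no combination")
        scan = ET.SubElement(scan_list, "scan")
        _cv(scan, "MS:1000016", "scan start time", f"{sp.rt:.6f}",
            unitCvRef="UO", unitAccession="UO:0000031", unitName="minute")
        if sp.ms_level >= 2:
            plist = ET.SubElement(el, "precursorList", count="1")
            prec = ET.SubElement(plist, "precursor")
            silist = ET.SubElement(prec, "selectedIonList", count="1")
            sion = ET.SubElement(silist, "selectedIon")
            _cv(sion, "MS:1000744", "selected ion m/z", f"{sp.precursor_mz:.6f}")
            act = ET.SubElement(prec, "activation")
            mode = sp.frag_mode or FragMode("unknown")
            if mode.technique == "HCD":
                _cv(act, "MS:1000422", "beam-type collision-induced dissociation")
                _cv(act, "MS:1000045", "collision energy", f"{mode.energy:g}")
            elif mode.technique == "UVPD":
                _cv(act, "MS:1003246", "ultraviolet photodissociation")
                ET.SubElement(
                    act, "userParam", name="reaction time", value=f"{mode.energy:g}",
                    unitName="millisecond",
                )
        bdal = ET.SubElement(el, "binaryDataArrayList", count="2")
        for accession, name, arr in (
            ("MS:1000514", "m/z array", sp.mz),
            ("MS:1000515", "intensity array", sp.intensity),
        ):
            payload = _b64(arr)
            bda = ET.SubElement(bdal, "binaryDataArray", encodedLength=str(len(payload)))
            _cv(bda, "MS:1000523", "64-bit float")
            _cv(bda, "MS:1000576", "no compression")
            _cv(bda, accession, name)
            ET.SubElement(bda, "binary").text = payload
    ET.indent(root)
    ET.ElementTree(root).write(str(path), xml_declaration=True, encoding="utf-8")


# ---------------------------------------------------------------------------
# Centroiding

def centroid_spectrum(
    mz: np.ndarray,
    intensity: np.ndarray,
    baseline: float = 0.0,
    max_gap: float = 0.05,
    sum_intensity: bool = False,
) -> Tuple[np.ndarray, np.ndarray]:
    """Reduce a profile spectrum to centroids.

    The spectrum is split into contiguous segments (points above
    ``baseline``, separated by at most ``max_gap`` in m/z); within each
    segment every local-maximum region between neighboring valleys becomes
    one centroid with intensity-weighted mean m/z.  Centroid intensity is
    the region's apex intensity by default (``sum_intensity=True`` sums it
    instead).  Already-centroided peak lists pass through unchanged because
    isolated points are their own segments.
    """
    mz = np.asarray(mz, dtype=np.float64)
    intensity = np.asarray(intensity, dtype=np.float64)
    if mz.size == 0:
        return np.empty(0), np.empty(0)
    keep = intensity > baseline
    out_mz: List[float] = []
    out_int: List[float] = []
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return np.empty(0), np.empty(0)
    # split indices into segments of consecutive points with small m/z gaps
    breaks = np.flatnonzero((np.diff(idx) > 1) | (np.diff(mz[idx]) > max_gap))
    segments = np.split(idx, breaks + 1)
    for seg in segments:
        y = intensity[seg]
        x = mz[seg]
        if seg.size <= 2:
            apex = int(np.argmax(y))
            w = y.sum()
            out_mz.append(float((x * y).sum() / w))
            out_int.append(float(y.sum() if sum_intensity else y[apex]))
            continue
        # local maxima within the segment
        peaks = [
            i for i in range(len(y))
            if (i == 0 or y[i] > y[i - 1]) and (i == len(y) - 1 or y[i] >= y[i + 1])
        ]
        # valley boundaries between consecutive peaks
        bounds = [0]
        for a, b in zip(peaks, peaks[1:]):
            bounds.append(a + int(np.argmin(y[a:b + 1])))
        bounds.append(len(y))
        for j, p in enumerate(peaks):
            lo = bounds[j] if j == 0 else bounds[j] + 1
            hi = bounds[j + 1]
            lo = min(lo, p)
            region = slice(lo, max(hi, p + 1))
            yr, xr = y[region], x[region]
            w = yr.sum()
            out_mz.append(float((xr * yr).sum() / w))
            out_int.append(float(yr.sum() if sum_intensity else y[p]))
    order = np.argsort(out_mz)
    return np.asarray(out_mz)[order], np.asarray(out_int)[order]


def centroided(sp: Spectrum, **kwargs) -> Spectrum:
    """Centroided copy of a scan (no-op copy if already centroided)."""
    if not sp.is_profile:
        return sp
    cmz, cint = centroid_spectrum(sp.mz, sp.intensity, **kwargs)
    return replace(sp, mz=cmz, intensity=cint, is_profile=False)


# ---------------------------------------------------------------------------
# Extracted ion chromatograms

@dataclass
class XIC:
    """Extracted ion chromatogram for one target m/z window."""

    target_mz: float
    tol_ppm: float
    rt: np.ndarray
    intensity: np.ndarray

    def apex(self) -> Tuple[float, float]:
        """(RT, intensity) of the global maximum; earliest RT on ties."""
        if self.rt.size == 0:
            raise ValueError("apex undefined: empty XIC")
        i = int(np.argmax(self.intensity))  # argmax returns first max
        return float(self.rt[i]), float(self.intensity[i])

    def peak_window(self, bound_frac: float = 0.05) -> Tuple[float, float]:
        """RT bounds of the contiguous region around the apex where the
        signal stays at or above ``bound_frac`` of the apex intensity."""
        if self.rt.size == 0:
            raise ValueError("peak window undefined: empty XIC")
        i = int(np.argmax(self.intensity))
        thr = bound_frac * self.intensity[i]
        lo = i
        while lo > 0 and self.intensity[lo - 1] >= thr and self.intensity[lo - 1] > 0:
            lo -= 1
        hi = i
        while hi < self.intensity.size - 1 and self.intensity[hi + 1] >= thr and self.intensity[hi + 1] > 0:
            hi += 1
        return float(self.rt[lo]), float(self.rt[hi])

    def auc(self, bound_frac: float = 0.05) -> float:
        """Trapezoidal area over the contiguous apex peak region."""
        if self.rt.size == 0 or float(self.intensity.max(initial=0.0)) <= 0.0:
            return 0.0
        lo_rt, hi_rt = self.peak_window(bound_frac)
        mask = (self.rt >= lo_rt) & (self.rt <= hi_rt)
        return float(np.trapezoid(self.intensity[mask], self.rt[mask]))

    def intensity_at(self, rt: float) -> float:
        """Intensity of the scan nearest in RT (the master intensity of an
        MS2 event at that retention time)."""
        if self.rt.size == 0:
            raise ValueError("empty XIC")
        return float(self.intensity[int(np.argmin(np.abs(self.rt - rt)))])


def xic(run: Run, target_mz: float, tol_ppm: float = 10.0, ms_level: int = 1) -> XIC:
    """Extract the chromatogram of ``target_mz`` +- ``tol_ppm`` at one MS level.

    Per-scan intensity is the sum of centroided intensities inside the
    window; profile scans are centroided on the fly.
    """
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    half = target_mz * tol_ppm * 1e-6
    rts: List[float] = []
    ints: List[float] = []
    for sp in run.ms_scans(ms_level):
        c = centroided(sp)
        lo = np.searchsorted(c.mz, target_mz - half, side="left")
        hi = np.searchsorted(c.mz, target_mz + half, side="right")
        rts.append(sp.rt)
        ints.append(float(c.intensity[lo:hi].sum()))
    return XIC(target_mz=target_mz, tol_ppm=tol_ppm,
               rt=np.asarray(rts), intensity=np.asarray(ints))


def select_top_ms2(
    run: Run,
    precursor_mz: float,
    precursor_xic: XIC,
    n: int = 3,
    tol_ppm: float = 10.0,
    bound_frac: float = 0.05,
    fallback_halfwidth: float = 0.5,
) -> Dict[FragMode, List[Spectrum]]:
    """Top-n MS2 scans near the chromatographic apex, per fragmentation mode.

    Candidate MS2 scans must match the precursor within ``tol_ppm`` and
    fall inside the apex peak window of the precursor XIC (falling back to
    apex +- ``fallback_halfwidth`` minutes when the window is degenerate).
    Within each mode the ``n`` scans of highest master intensity (the
    precursor's MS1 XIC intensity at the nearest RT) are kept; fewer are
    returned when fewer exist.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    apex_rt, apex_int = precursor_xic.apex()
    if apex_int > 0:
        lo, hi = precursor_xic.peak_window(bound_frac)
        if hi - lo <= 0:
            lo, hi = apex_rt - fallback_halfwidth, apex_rt + fallback_halfwidth
    else:
        lo, hi = apex_rt - fallback_halfwidth, apex_rt + fallback_halfwidth
    half = precursor_mz * tol_ppm * 1e-6
    by_mode: Dict[FragMode, List[Tuple[float, float, Spectrum]]] = {}
    for sp in run.ms_scans(2):
        if sp.precursor_mz is None or abs(sp.precursor_mz - precursor_mz) > half:
            continue
        if not (lo - 1e-9 <= sp.rt <= hi + 1e-9):
            continue
        master = precursor_xic.intensity_at(sp.rt)
        mode = sp.frag_mode or FragMode("unknown")
        by_mode.setdefault(mode, []).append((master, sp.rt, sp))
    out: Dict[FragMode, List[Spectrum]] = {}
    for mode, cands in by_mode.items():
        # highest master intensity first; earlier RT breaks ties
        cands.sort(key=lambda t: (-t[0], t[1]))
        out[mode] = [c[2] for c in cands[:n]]
    return out
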