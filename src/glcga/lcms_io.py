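"""LC-MS run model and I/O: mzML reading/writing, XIC extraction, peak picking.

A :class:`Run` holds centroided MS1 full scans plus DDA MS2 spectra.  XICs
are per-scan summed intensities inside a narrow ppm window; chromatographic
peaks are picked from a moving-average-smoothed trace with an MAD noise
estimate and quadratic apex interpolation (sub-scan RT accuracy matters
because the light/heavy pairing criterion is 0-0.013 min).
"""

from __future__ import annotations

import base64
import struct
import warnings
import zlib
from dataclasses import dataclass, field
from typing import List, Optional, Tuple
from xml.etree import ElementTree
from xml.sax.saxutils import escape

import numpy as np

__all__ = [
    "MS1Spectrum",
    "MS2Spectrum",
    "Run",
    "XICTrace",
    "ChromPeak",
    "read_run",
    "write_mzml",
    "extract_xic",
    "detect_peaks",
    "ms2_near",
]


@dataclass
class MS1Spectrum:
    """A centroided full scan: sorted m/z array with intensities, RT in min."""

    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            order = np.argsort(self.mz)
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")


@dataclass
class MS2Spectrum:
    """A DDA fragment spectrum tied to a precursor m/z and RT."""

    precursor_mz: float
    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            order = np.argsort(self.mz)
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


@dataclass
class Run:
    """An LC-MS run: RT-ordered MS1 scans plus an MS2 list."""

    ms1: List[MS1Spectrum] = field(default_factory=list)
    ms2: List[MS2Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.ms1]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("MS1 retention times must be non-decreasing")

    @property
    def rt_array(self) -> np.ndarray:
        return np.array([s.rt for s in self.ms1])


@dataclass
class XICTrace:
    """Extracted ion chromatogram for one target m/z window."""

    target_mz: float
    tol_ppm: float
    rt: np.ndarray
    intensity: np.ndarray


@dataclass
class ChromPeak:
    """A detected chromatographic peak (bounds are RT minutes)."""

    rt: float  # interpolated apex RT
    height: float
    area: float
    left: float
    right: float
    snr: float


# ---------------------------------------------------------------------------
# mzML I/O


_NS = "{http://psi.hupo.org/ms/mzml}"

# cv accessions used by the narrow mzML parser
_ACC_MS_LEVEL = "MS:1000511"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"


def _cv_params(element) -> dict:
    return {
        cv.get("accession"): cv
        for cv in element.iter(_NS + "cvParam")
    }


def _decode_binary_array(bda) -> np.ndarray:
    params = _cv_params(bda)
    binary = bda.find(_NS + "binary")
    if binary is None or not (binary.text or "").strip():
        return np.empty(0)
    raw = base64.b64decode(binary.text)
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    dtype = np.float32 if _ACC_F32 in params else np.float64
    return np.frombuffer(raw, dtype=np.dtype(dtype).newbyteorder("<")).astype(float)


def read_run(path) -> Run:
    """Read a centroided mzML file (MS1 + MS2) into a :class:`Run`.

    A deliberately narrow parser for standard mzML: 32/64-bit float arrays,
    plain or zlib-compressed, MS1/MS2 levels, scan start time in minutes or
    seconds, one selected ion per MS2 precursor.  Profile-mode spectra are
    accepted with a warning (points used as centroids).  Raises
    ``ValueError`` on unparsable/truncated files.
    """
    ms1: List[MS1Spectrum] = []
    ms2: List[MS2Spectrum] = []
    try:
        context = ElementTree.iterparse(str(path), events=("end",))
        for _event, element in context:
            if element.tag != _NS + "spectrum":
                continue
            params = _cv_params(element)
            if _ACC_PROFILE in params:
                warnings.warn("profile-mode spectrum encountered; using points as centroids")
            level = int(params[_ACC_MS_LEVEL].get("value", "1")) if _ACC_MS_LEVEL in params else 1
            rt = 0.0
            scan = element.find(f"{_NS}scanList/{_NS}scan")
            if scan is not None:
                sp = _cv_params(scan)
                if _ACC_SCAN_START in sp:
                    rt = float(sp[_ACC_SCAN_START].get("value"))
                    if sp[_ACC_SCAN_START].get("unitName", "minute") == "second":
                        rt /= 60.0
            mz = intensity = None
            for bda in element.iter(_NS + "binaryDataArray"):
                p = _cv_params(bda)
                if _ACC_MZ_ARRAY in p:
                    mz = _decode_binary_array(bda)
                elif _ACC_INT_ARRAY in p:
                    intensity = _decode_binary_array(bda)
            if mz is None or intensity is None:
                raise ValueError(f"spectrum without m/z or intensity array in {path}")
            if level == 2:
                ion = element.find(
                    f"{_NS}precursorList/{_NS}precursor/{_NS}selectedIonList/{_NS}selectedIon"
                )
                if ion is None:
                    raise ValueError(f"MS2 spectrum without precursor in {path}")
                prec = float(_cv_params(ion)[_ACC_SELECTED_MZ].get("value"))
                ms2.append(MS2Spectrum(prec, rt, mz, intensity))
            else:
                ms1.append(MS1Spectrum(rt, mz, intensity))
            element.clear()
    except ElementTree.ParseError as exc:
        raise ValueError(f"unreadable or truncated mzML file {path}: {exc}") from exc
    ms1.sort(key=lambda s: s.rt)
    return Run(ms1=ms1, ms2=ms2)


def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *np.asarray(values, dtype=float))
    return base64.b64encode(raw).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="glcga" version="0.1.0"/>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1"/>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1">
      <processingMethod order="1" softwareRef="glcga">
        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
  <run id="{run_id}" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count="{count}" defaultDataProcessingRef="DP1">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _binary_block(name: str, accession: str, values: np.ndarray) -> str:
    payload = _encode_array(values)
    return (
        f'          <binaryDataArray encodedLength="{len(payload)}">\n'
        '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
        '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
        f'            <cvParam cvRef="MS" accession="{accession}" name="{name}" value=""/>\n'
        f"            <binary>{payload}</binary>\n"
        "          </binaryDataArray>\n"
    )


def write_mzml(run: Run, path, run_id: str = "simulated-run") -> None:
    """Write a Run as minimal standard mzML (64-bit floats, no compression).

    The output is deterministic (no timestamps) and round-trips through
    :func:`read_run` / pyteomics.
    """
    spectra: List[Tuple[float, int, object]] = [(s.rt, 1, s) for s in run.ms1]
    spectra += [(s.rt, 2, s) for s in run.ms2]
    spectra.sort(key=lambda t: (t[0], t[1]))
    chunks = [_MZML_HEADER.format(run_id=escape(run_id), count=len(spectra))]
    for index, (rt, level, spec) in enumerate(spectra):
        chunks.append(
            f'      <spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{spec.mz.size}">\n'
            f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{level}"/>\n'
            '        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>\n'
            '        <scanList count="1">\n'
            "          <scan>\n"
            f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt:.6f}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>\n'
            "          </scan>\n"
            "        </scanList>\n"
        )
        if level == 2:
            chunks.append(
                '        <precursorList count="1">\n'
                "          <precursor>\n"
                '            <selectedIonList count="1">\n'
                "              <selectedIon>\n"
                f'                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{spec.precursor_mz:.6f}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
                "              </selectedIon>\n"
                "            </selectedIonList>\n"
                "          </precursor>\n"
                "        </precursorList>\n"
            )
        chunks.append('        <binaryDataArrayList count="2">\n')
        chunks.append(_binary_block("m/z array", "MS:1000514", spec.mz))
        chunks.append(_binary_block("intensity array", "MS:1000515", spec.intensity))
        chunks.append("        </binaryDataArrayList>\n      </spectrum>\n")
    chunks.append(_MZML_FOOTER)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("".join(chunks))


# ---------------------------------------------------------------------------
# XIC extraction and peak detection


def extract_xic(run: Run, mz: float, tol_ppm: float = 10.0) -> XICTrace:
    """Per-MS1-scan summed intensity within +- tol_ppm of the target m/z."""
    half = mz * tol_ppm * 1e-6
    lo, hi = mz - half, mz + half
    rts = np.empty(len(run.ms1))
    vals = np.zeros(len(run.ms1))
    for i, scan in enumerate(run.ms1):
        rts[i] = scan.rt
        a = np.searchsorted(scan.mz, lo, side="left")
        b = np.searchsorted(scan.mz, hi, side="right")
        if b > a:
            vals[i] = scan.intensity[a:b].sum()
    return XICTrace(target_mz=mz, tol_ppm=tol_ppm, rt=rts, intensity=vals)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or x.size < window:
        return x.astype(float)
    kernel = np.ones(window)
    smoothed = np.convolve(x, kernel, mode="same")
    norm = np.convolve(np.ones_like(x), kernel, mode="same")
    return smoothed / norm


def detect_peaks(
    trace: XICTrace,
    min_snr: float = 3.0,
    min_points: int = 5,
    smooth_window: int = 5,
) -> List[ChromPeak]:
    """Pick chromatographic peaks from an XIC.

    Smoothing: moving average (default 5 scans).  The median of the trace is
    taken as the baseline; noise is 1.4826 x MAD about it (floored at 1
    count so blank traces don't divide by zero); heights are
    baseline-subtracted.
    Apex: local maximum of the smoothed trace refined by a three-point
    quadratic fit; bounds extend to the flanking valleys.  Peaks narrower
    than ``min_points`` scans or below ``min_snr`` are dropped.
    """
    raw = np.asarray(trace.intensity, dtype=float)
    rt = np.asarray(trace.rt, dtype=float)
    if raw.size == 0:
        return []
    baseline = float(np.median(raw))
    y = raw - baseline
    smoothed = _moving_average(y, smooth_window)
    mad = np.median(np.abs(y))
    noise = max(1.4826 * mad, 1.0)
    threshold = min_snr * noise

    peaks: List[ChromPeak] = []
    n = y.size
    for i in range(1, n - 1):
        if not (smoothed[i] >= smoothed[i - 1] and smoothed[i] > smoothed[i + 1]):
            continue
        if smoothed[i] < threshold or smoothed[i] <= 0:
            continue
        left = i
        while left > 0 and 0 < smoothed[left - 1] <= smoothed[left]:
            left -= 1
        right = i
        while right < n - 1 and 0 < smoothed[right + 1] <= smoothed[right]:
            right += 1
        if right - left + 1 < min_points:
            continue
        apex_rt = _quadratic_apex(rt, smoothed, i)
        apex_rt = float(np.clip(apex_rt, rt[left], rt[right]))
        height = float(smoothed[i])
        area = float(np.trapezoid(y[left : right + 1], rt[left : right + 1]))
        peaks.append(
            ChromPeak(
                rt=apex_rt,
                height=height,
                area=area,
                left=float(rt[left]),
                right=float(rt[right]),
                snr=height / noise,
            )
        )
    peaks.sort(key=lambda p: p.rt)
    return peaks


def _quadratic_apex(rt: np.ndarray, y: np.ndarray, i: int) -> float:
    if i == 0 or i == y.size - 1:
        return float(rt[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom >= 0:
        return float(rt[i])
    shift = 0.5 * (y[i - 1] - y[i + 1]) / denom
    shift = float(np.clip(shift, -0.5, 0.5))
    step = 0.5 * (rt[min(i + 1, y.size - 1)] - rt[max(i - 1, 0)])
    return float(rt[i] + shift * step)


def ms2_near(
    run: Run,
    precursor_mz: float,
    rt: float,
    tol_ppm: float = 10.0,
    rt_window: float = 0.2,
) -> Optional[MS2Spectrum]:
    """The MS2 spectrum nearest in RT whose precursor matches within tol.

    Ties in |deltaRT| break toward the higher total ion current.
    """
    half = precursor_mz * tol_ppm * 1e-6
    best: Optional[MS2Spectrum] = None
    best_key: Optional[Tuple[float, float]] = None
    for spec in run.ms2:
        if abs(spec.precursor_mz - precursor_mz) > half:
            continue
        drt = abs(spec.rt - rt)
        if drt > rt_window:
            continue
        key = (drt, -spec.tic)
        if best_key is None or key < best_key:
            best, best_key = spec, key
    return best
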