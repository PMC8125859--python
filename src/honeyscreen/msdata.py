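"""Centroided two-channel DIA runs: mzML I/O, EIC extraction, peak detection.

A run holds two retention-time-ordered spectrum lists: a low-collision-energy
channel (precursor, "MS") and a high-collision-energy channel (fragment,
"MS/MS"), as produced by broadband-CID data-independent acquisition.
Retention times are minutes throughout; m/z tolerances are millidaltons.

Both directions use a self-contained centroid-only mzML layer
(uncompressed or zlib-compressed little-endian float32/float64 arrays,
identified by the usual PSI-MS cvParam accessions), so runs round-trip
losslessly without any vendor tooling.
"""

from __future__ import annotations

import base64
import struct
import warnings
import zlib
from dataclasses import dataclass, field
from xml.etree import ElementTree as ET
from xml.sax.saxutils import escape

import numpy as np

__all__ = [
    "Spectrum",
    "Run",
    "EIC",
    "ChromPeak",
    "read_run",
    "write_mzml",
    "extract_eic",
    "detect_peaks",
    "msms_for_peak",
    "eic_to_csv",
    "peaks_to_csv",
]

LOW_ENERGY_EV = 4.0
HIGH_ENERGY_EV = 25.0
#: collision energies at or above this are assigned to the fragment channel
_CHANNEL_SPLIT_EV = 10.0


@dataclass
class Spectrum:
    """One centroided scan: sorted m/z array with aligned intensities."""

    rt: float  # minutes
    channel: str  # "low" or "high"
    mzs: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.mzs = np.asarray(self.mzs, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mzs.shape != self.intensities.shape:
            raise ValueError("m/z and intensity arrays must align")
        if self.mzs.size > 1 and not np.all(np.diff(self.mzs) > 0):
            raise ValueError("centroid m/z values must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("negative intensities")
        if self.rt < 0:
            raise ValueError("negative retention time")
        if self.channel not in ("low", "high"):
            raise ValueError(f"unknown channel {self.channel!r}")


@dataclass
class Run:
    """rt-ordered DIA run with sample metadata."""

    low: list[Spectrum] = field(default_factory=list)
    high: list[Spectrum] = field(default_factory=list)
    sample_id: str = ""
    sample_role: str = "sample"  # sample | blank | QC
    class_label: str | None = None
    mz_range: tuple[float, float] = (50.0, 1000.0)

    def __post_init__(self) -> None:
        for spectra in (self.low, self.high):
            rts = [s.rt for s in spectra]
            if rts != sorted(rts):
                raise ValueError("spectra must be rt-ordered within channel")


@dataclass
class EIC:
    """Extracted ion chromatogram for a narrow m/z window."""

    target_mz: float
    tol_mda: float
    rts: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.rts = np.asarray(self.rts, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.rts.shape != self.intensities.shape:
            raise ValueError("rt and intensity arrays must align")


@dataclass
class ChromPeak:
    rt_apex: float
    height: float
    area: float  # counts × minutes, trapezoid over bounds
    snr: float
    bounds: tuple[float, float]

    def __post_init__(self) -> None:
        start, end = self.bounds
        if not start < self.rt_apex < end:
            raise ValueError("apex must lie strictly inside the bounds")


# ---------------------------------------------------------------------------
# mzML I/O

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="{run_id}">
    <spectrumList count="{count}">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(raw).decode("ascii")


def _spectrum_xml(spectrum: Spectrum, index: int) -> str:
    ms_level = 1 if spectrum.channel == "low" else 2
    energy = LOW_ENERGY_EV if spectrum.channel == "low" else HIGH_ENERGY_EV
    n = len(spectrum.mzs)
    mz_b64 = _encode_array(spectrum.mzs)
    int_b64 = _encode_array(spectrum.intensities)
    precursor = ""
    if spectrum.channel == "high":
        precursor = f"""        <precursorList count="1">
          <precursor>
            <activation>
              <cvParam cvRef="MS" accession="MS:1000045" name="collision energy" value="{energy}" unitName="electronvolt"/>
            </activation>
          </precursor>
        </precursorList>
"""
    return f"""      <spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{spectrum.rt!r}" unitName="minute"/>
          </scan>
        </scanList>
{precursor}        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(int_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""


def write_mzml(run: Run, path: str) -> None:
    """Write a centroid run as minimal mzML (readable by pyteomics)."""
    spectra = sorted(run.low + run.high, key=lambda s: (s.rt, s.channel))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            _MZML_HEADER.format(
                run_id=escape(run.sample_id or "run", {'"': "&quot;"}),
                count=len(spectra),
            )
        )
        for i, spectrum in enumerate(spectra):
            fh.write(_spectrum_xml(spectrum, i))
        fh.write(_MZML_FOOTER)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_array(binary_el, params: dict[str, str]) -> np.ndarray:
    text = (binary_el.text or "").strip()
    raw = base64.b64decode(text) if text else b""
    if "MS:1000574" in params:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in params else "<f8"  # 32- vs 64-bit float
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum_element(el) -> Spectrum:
    accessions: dict[str, str] = {}
    rt = None
    energy = None
    ms_level = 1
    arrays: dict[str, np.ndarray] = {}
    for cv in el.iter():
        if _local(cv.tag) != "cvParam":
            continue
        accessions[cv.get("accession", "")] = cv.get("value", "")
    if "MS:1000128" in accessions:
        raise ValueError("profile-mode data is not supported; centroid first")
    if "MS:1000511" in accessions:
        ms_level = int(accessions["MS:1000511"])
    if "MS:1000045" in accessions:
        energy = float(accessions["MS:1000045"])
    for scan in el.iter():
        if _local(scan.tag) != "scan":
            continue
        for cv in scan:
            if _local(cv.tag) == "cvParam" and cv.get("accession") == "MS:1000016":
                value = float(cv.get("value"))
                unit = cv.get("unitName", "minute")
                rt = value / 60.0 if unit.startswith("second") else value
        break
    for bda in el.iter():
        if _local(bda.tag) != "binaryDataArray":
            continue
        local_params: dict[str, str] = {}
        binary_el = None
        for child in bda:
            if _local(child.tag) == "cvParam":
                local_params[child.get("accession", "")] = child.get("value", "")
            elif _local(child.tag) == "binary":
                binary_el = child
        if binary_el is None:
            raise ValueError("binaryDataArray without binary payload")
        data = _decode_array(binary_el, local_params)
        if "MS:1000514" in local_params:
            arrays["mz"] = data
        elif "MS:1000515" in local_params:
            arrays["intensity"] = data
    if rt is None or "mz" not in arrays or "intensity" not in arrays:
        raise ValueError("spectrum missing scan time or data arrays")
    if energy is not None:
        channel = "high" if energy >= _CHANNEL_SPLIT_EV else "low"
    else:
        channel = "high" if ms_level >= 2 else "low"
    return Spectrum(
        rt=rt, channel=channel, mzs=arrays["mz"], intensities=arrays["intensity"]
    )


def read_run(
    path: str,
    sample_id: str = "",
    sample_role: str = "sample",
    class_label: str | None = None,
) -> Run:
    """Read a centroided mzML file into a two-channel :class:`Run`.

    Channel assignment follows the collision-energy metadata (4 eV → low
    / precursor channel, 25 eV → high / fragment channel); when no energy
    is recorded the ms level is used instead.  Profile-mode spectra are
    rejected.
    """
    low: list[Spectrum] = []
    high: list[Spectrum] = []
    try:
        for _, el in ET.iterparse(path):
            if _local(el.tag) != "spectrum":
                continue
            spectrum = _parse_spectrum_element(el)
            (high if spectrum.channel == "high" else low).append(spectrum)
            el.clear()
    except ET.ParseError as exc:
        raise OSError(f"unreadable mzML file {path!r}: {exc}") from exc
    if not low and not high:
        raise OSError(f"no spectra found in {path!r}")
    if not high:
        warnings.warn("run has no high-energy (fragment) channel", stacklevel=2)
    low.sort(key=lambda s: s.rt)
    high.sort(key=lambda s: s.rt)
    return Run(
        low=low,
        high=high,
        sample_id=sample_id,
        sample_role=sample_role,
        class_label=class_label,
    )


# ---------------------------------------------------------------------------
# chromatogram extraction and peak detection


def extract_eic(run: Run, mz: float, tol_mda: float = 5.0) -> EIC:
    """Sum centroids within ±tol of the target m/z, per low-energy scan."""
    if not run.low:
        raise ValueError("run has no low-energy spectra")
    tol = tol_mda * 1e-3
    rts = np.array([s.rt for s in run.low])
    intensities = np.empty(len(run.low))
    for i, spectrum in enumerate(run.low):
        lo = np.searchsorted(spectrum.mzs, mz - tol, side="left")
        hi = np.searchsorted(spectrum.mzs, mz + tol, side="right")
        intensities[i] = spectrum.intensities[lo:hi].sum()
    return EIC(target_mz=mz, tol_mda=tol_mda, rts=rts, intensities=intensities)


def _descend(y: np.ndarray, apex: int, step: int, floor: float = 0.0) -> int:
    """Walk from the apex until a valley or the baseline floor is reached."""
    i = apex
    while True:
        nxt = i + step
        if nxt < 0 or nxt >= len(y):
            break
        if y[nxt] > y[i]:
            break  # surrounding valley
        i = nxt
        if y[i] <= floor:
            break  # baseline
    return i


def detect_peaks(eic: EIC, snr_min: float = 3.0) -> list[ChromPeak]:
    """Simple apex/valley detector on an EIC.

    Local maxima are kept when their height exceeds ``snr_min`` × noise,
    where noise is 1.4826 × the median absolute deviation of the off-peak
    signal (floored at 1 count).  Boundaries extend to the surrounding
    valleys or baseline; areas are trapezoids over the bounds.
    """
    y = eic.intensities
    t = eic.rts
    if len(y) < 5:
        raise ValueError("trace too short for peak detection (need ≥5 points)")
    apices = [
        i
        for i in range(1, len(y) - 1)
        if y[i] > 0 and y[i] >= y[i - 1] and y[i] > y[i + 1]
    ]
    candidates = []
    covered = np.zeros(len(y), dtype=bool)
    for apex in apices:
        floor = 1e-3 * y[apex]  # bound crawl along a flat baseline
        left = _descend(y, apex, -1, floor)
        right = _descend(y, apex, +1, floor)
        if left == apex or right == apex:
            continue
        candidates.append((apex, left, right))
        covered[left : right + 1] = True
    off_peak = y[~covered]
    if off_peak.size:
        mad = np.median(np.abs(off_peak - np.median(off_peak)))
        noise = max(1.4826 * mad, 1.0)
    else:
        noise = 1.0
    peaks = []
    for apex, left, right in candidates:
        height = float(y[apex])
        snr = height / noise
        if snr < snr_min:
            continue
        area = float(np.trapezoid(y[left : right + 1], t[left : right + 1]))
        peaks.append(
            ChromPeak(
                rt_apex=float(t[apex]),
                height=height,
                area=area,
                snr=snr,
                bounds=(float(t[left]), float(t[right])),
            )
        )
    return peaks


def eic_to_csv(eic: EIC, path: str) -> None:
    """Write the trace as CSV (columns rt_min, intensity)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rt_min,intensity\n")
        for t, y in zip(eic.rts, eic.intensities):
            fh.write(f"{float(t)!r},{float(y)!r}\n")


def peaks_to_csv(peaks: list[ChromPeak], path: str) -> None:
    """Write detected peaks as CSV (one row per peak)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rt_apex,height,area,snr,rt_start,rt_end\n")
        for p in peaks:
            fh.write(
                f"{float(p.rt_apex)!r},{float(p.height)!r},{float(p.area)!r},"
                f"{float(p.snr)!r},{float(p.bounds[0])!r},{float(p.bounds[1])!r}\n"
            )


def _average_channel(
    spectra: list[Spectrum], tol_mda: float
) -> tuple[np.ndarray, np.ndarray]:
    """Average centroid spectra by gap-clustering m/z within tolerance."""
    if not spectra:
        return np.empty(0), np.empty(0)
    mzs = np.concatenate([s.mzs for s in spectra])
    ints = np.concatenate([s.intensities for s in spectra])
    if mzs.size == 0:
        return np.empty(0), np.empty(0)
    order = np.argsort(mzs)
    mzs, ints = mzs[order], ints[order]
    breaks = np.where(np.diff(mzs) > tol_mda * 1e-3)[0] + 1
    groups = np.split(np.arange(len(mzs)), breaks)
    out_mz = np.array([np.average(mzs[g], weights=np.maximum(ints[g], 1e-12)) for g in groups])
    out_int = np.array([ints[g].sum() / len(spectra) for g in groups])
    return out_mz, out_int


def msms_for_peak(
    run: Run,
    peak: ChromPeak,
    precursor_mz: float,
    background_width: float = 0.2,
    tol_mda: float = 5.0,
) -> Spectrum:
    """Background-subtracted fragment spectrum over the peak's rt bounds.

    High-energy spectra inside the bounds are averaged; the average of the
    flanking background windows (``background_width`` minutes on each
    side) is subtracted and negative intensities are clipped to zero.
    """
    if not run.high:
        raise ValueError("run has no high-energy spectra")
    start, end = peak.bounds
    inside = [s for s in run.high if start <= s.rt <= end]
    if not inside:
        raise ValueError("no high-energy spectra within peak bounds")
    flank = [
        s
        for s in run.high
        if (start - background_width <= s.rt < start)
        or (end < s.rt <= end + background_width)
    ]
    mz_in, int_in = _average_channel(inside, tol_mda)
    mz_bg, int_bg = _average_channel(flank, tol_mda)
    # subtract background intensity from the nearest matched cluster
    for j, mz in enumerate(mz_bg):
        if mz_in.size == 0:
            break
        k = int(np.argmin(np.abs(mz_in - mz)))
        if abs(mz_in[k] - mz) <= tol_mda * 1e-3:
            int_in[k] -= int_bg[j]
    keep = int_in > 0
    return Spectrum(
        rt=peak.rt_apex, channel="high", mzs=mz_in[keep], intensities=int_in[keep]
    )
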