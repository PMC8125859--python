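"""Target and suspect screening of DIA runs.

Target screening confirms compounds against reference-standard criteria
(retention time ±0.2 min, precursor and qualifier mass accuracy < 5 mDa,
isotopic-fit surrogate ≤ 50, at least two qualifier ions) and quantifies
them on matrix-matched calibration curves.  Suspect screening applies the
intensity (> 1000 counts), peak-area (> 2000), mass-accuracy and
isotopic-fit thresholds, checks the experimental retention time against a
QSRR-predicted one (window 1.8 min) and evaluates MS/MS evidence, ending
in a Schymanski-style identification confidence level (1, 2a, 2b, 3, 4, 5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .chem import (
    IsotopePattern,
    MassError,
    MolecularFormula,
    ion_isotope_pattern,
    isotopic_fit,
    mass_error,
    parse_formula,
    pseudomolecular_mz,
)
from .msdata import ChromPeak, Run, Spectrum, detect_peaks, extract_eic, msms_for_peak

__all__ = [
    "TargetEntry",
    "SuspectEntry",
    "Detection",
    "CalibrationCurve",
    "BELOW_LOD",
    "screen_targets",
    "fit_calibration",
    "quantify",
    "validation_metrics",
    "screen_suspects",
    "resolve_isomers",
    "match_msms",
    "assign_confidence",
    "measured_pattern_for_peak",
    "load_target_list",
    "load_suspect_list",
    "load_library",
    "detections_to_frame",
]

# study-default screening thresholds (all configurable per call)
RT_TOL_TARGET = 0.2  # min, ± window for target screening
MASS_TOL_MDA = 5.0
MSIGMA_MAX = 50.0
MIN_INTENSITY = 1000.0  # strict: height must exceed this
MIN_AREA = 2000.0  # strict: trapezoid area must exceed this
RT_WINDOW_SUSPECT = 1.8  # min, |experimental − predicted|
SIMILARITY_MIN = 0.7
MIN_MATCHED_FRAGMENTS = 3  # fallback when the library spectrum has no intensities


class _BelowLOD:
    """Sentinel for quantification results below the detection limit."""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "<LOD"


BELOW_LOD = _BelowLOD()


@dataclass
class TargetEntry:
    name: str
    formula: MolecularFormula | str
    rt_expected: float
    precursor_mz: float | None = None
    qualifier_ions: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if isinstance(self.formula, str):
            self.formula = parse_formula(self.formula)
        theoretical = pseudomolecular_mz(self.formula)
        if self.precursor_mz is None:
            self.precursor_mz = theoretical
        elif abs(self.precursor_mz - theoretical) > 1e-3:
            raise ValueError(
                f"{self.name}: precursor m/z {self.precursor_mz} inconsistent "
                f"with [M-H]- of {self.formula} ({theoretical:.4f})"
            )
        if len(self.qualifier_ions) < 2:
            raise ValueError(f"{self.name}: at least two qualifier ions required")


@dataclass
class SuspectEntry:
    name: str
    formula: MolecularFormula | str
    rt_predicted: float | None = None
    expected_fragments: list[float] = field(default_factory=list)
    library_spectrum: Spectrum | None = None

    def __post_init__(self) -> None:
        if isinstance(self.formula, str):
            self.formula = parse_formula(self.formula)
        if self.rt_predicted is not None and self.rt_predicted <= 0:
            raise ValueError(f"{self.name}: rt_predicted must be positive")

    @property
    def precursor_mz(self) -> float:
        return pseudomolecular_mz(self.formula)


@dataclass
class Detection:
    """A compound hit together with the evidence that produced it."""

    name: str
    peak: ChromPeak
    mass_error: MassError | None = None
    isotopic_fit: float | None = None  # mSigma-like surrogate, lower is better
    matched_fragments: list[float] = field(default_factory=list)
    rt_error: float | None = None  # minutes, experimental − expected/predicted
    similarity: float | None = None
    confidence_level: str = "5"
    formula: MolecularFormula | None = None
    measured_mz: float | None = None
    n_expected_fragments: int | None = None


@dataclass
class CalibrationCurve:
    levels: list[tuple[float, float]]  # (concentration mg/L, response)
    slope: float
    intercept: float
    r2: float
    mode: str = "matrix-matched"  # or "solvent"
    residual_sd: float = 0.0  # s_y/x

    @property
    def lod(self) -> float:
        """3.3 × s_y/x / slope (residual-SD method)."""
        return 3.3 * self.residual_sd / self.slope

    @property
    def loq(self) -> float:
        """10 × s_y/x / slope."""
        return 10.0 * self.residual_sd / self.slope


# ---------------------------------------------------------------------------
# evidence extraction helpers


def _measured_mz(run: Run, peak: ChromPeak, mz: float, tol_mda: float) -> float | None:
    """Intensity-weighted centroid m/z near the apex, within the window."""
    spectrum = min(run.low, key=lambda s: abs(s.rt - peak.rt_apex))
    tol = tol_mda * 1e-3
    lo = np.searchsorted(spectrum.mzs, mz - tol, "left")
    hi = np.searchsorted(spectrum.mzs, mz + tol, "right")
    if hi <= lo:
        return None
    weights = spectrum.intensities[lo:hi]
    return float(np.average(spectrum.mzs[lo:hi], weights=np.maximum(weights, 1e-12)))


def measured_pattern_for_peak(
    run: Run, peak: ChromPeak, theoretical: IsotopePattern, tol_mda: float = 5.0
) -> IsotopePattern | None:
    """Extract the experimental isotope pattern at the peak apex.

    For every theoretical peak position, centroids within the tolerance
    window of the apex scan are summed; abundances are normalised to the
    base peak.
    """
    spectrum = min(run.low, key=lambda s: abs(s.rt - peak.rt_apex))
    tol = tol_mda * 1e-3
    masses, abundances = [], []
    for mass, _ in theoretical.peaks:
        lo = np.searchsorted(spectrum.mzs, mass - tol, "left")
        hi = np.searchsorted(spectrum.mzs, mass + tol, "right")
        total = float(spectrum.intensities[lo:hi].sum())
        if total > 0:
            masses.append(mass)
            abundances.append(total)
    if not abundances:
        return None
    base = max(abundances)
    return IsotopePattern(
        peaks=tuple((m, a / base) for m, a in zip(masses, abundances))
    )


# ---------------------------------------------------------------------------
# target screening


def screen_targets(
    run: Run,
    targets: list[TargetEntry],
    rt_tol: float = RT_TOL_TARGET,
    mass_tol_mda: float = MASS_TOL_MDA,
    msigma_max: float = MSIGMA_MAX,
    min_qualifiers: int = 2,
) -> list[Detection]:
    """Reference-standard identification: all four criteria must hold.

    A detection is emitted iff the peak lies within ±rt_tol of the
    expected retention time, the precursor mass error is below the
    tolerance, the isotopic-fit surrogate is ≤ msigma_max, and at least
    ``min_qualifiers`` qualifier ions are found in the fragment channel.
    """
    detections: list[Detection] = []
    for target in targets:
        theoretical_mz = pseudomolecular_mz(target.formula)
        eic = extract_eic(run, theoretical_mz, mass_tol_mda)
        theo_pattern = ion_isotope_pattern(target.formula)
        for peak in detect_peaks(eic):
            rt_err = peak.rt_apex - target.rt_expected
            if abs(rt_err) >= rt_tol:
                continue
            measured = _measured_mz(run, peak, theoretical_mz, mass_tol_mda)
            if measured is None:
                continue
            err = mass_error(measured, theoretical_mz)
            if abs(err.mda) >= mass_tol_mda:
                continue
            measured_pattern = measured_pattern_for_peak(
                run, peak, theo_pattern, mass_tol_mda
            )
            if measured_pattern is None:
                continue
            msigma, _ = isotopic_fit(measured_pattern, theo_pattern)
            if msigma > msigma_max:
                continue
            try:
                msms = msms_for_peak(run, peak, theoretical_mz)
            except ValueError:
                continue
            matched = [
                q
                for q in target.qualifier_ions
                if msms.mzs.size
                and np.min(np.abs(msms.mzs - q)) <= mass_tol_mda * 1e-3
            ]
            if len(matched) < min_qualifiers:
                continue
            detections.append(
                Detection(
                    name=target.name,
                    peak=peak,
                    mass_error=err,
                    isotopic_fit=msigma,
                    matched_fragments=matched,
                    rt_error=rt_err,
                    confidence_level="1",
                    formula=target.formula,
                    measured_mz=measured,
                )
            )
    return detections


# ---------------------------------------------------------------------------
# calibration and quantification


def fit_calibration(
    levels: list[tuple[float, float]], mode: str = "matrix-matched"
) -> CalibrationCurve:
    """Ordinary least squares of response on concentration (≥4 levels)."""
    concs = np.array([c for c, _ in levels], dtype=float)
    resps = np.array([r for _, r in levels], dtype=float)
    if len(set(concs.tolist())) < 4:
        raise ValueError("need at least 4 distinct concentration levels")
    if np.ptp(concs) == 0:
        raise ValueError("zero variance in concentrations")
    fit = _stats.linregress(concs, resps)
    fitted = fit.intercept + fit.slope * concs
    dof = max(len(concs) - 2, 1)
    residual_sd = math.sqrt(float(np.sum((resps - fitted) ** 2)) / dof)
    return CalibrationCurve(
        levels=list(levels),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        mode=mode,
        residual_sd=residual_sd,
    )


def quantify(
    detection: Detection | float, curve: CalibrationCurve, dilution: float = 0.2
):
    """Concentration in honey (mg/kg) from peak area and calibration.

    ``dilution`` converts extract mg/L to honey mg/kg; the default 0.2
    reflects reconstituting 1 g of honey into 0.2 mL of extract.  Responses
    at or below the intercept return the ``BELOW_LOD`` sentinel rather
    than a negative concentration.
    """
    if curve.slope == 0:
        raise ValueError("calibration slope is zero")
    response = detection.peak.area if isinstance(detection, Detection) else detection
    conc_extract = (response - curve.intercept) / curve.slope
    if conc_extract <= 0:
        return BELOW_LOD
    return conc_extract * dilution


def validation_metrics(
    spiked: list[float],
    reference: float,
    curves: tuple[CalibrationCurve, CalibrationCurve] | None = None,
) -> dict[str, float]:
    """Recovery %, matrix effect %, RSD %, LOD and LOQ.

    recovery% = 100 × mean(spiked responses) / matrix-matched reference
    response at the same concentration; ME% = 100 × (matrix slope /
    solvent slope − 1); RSD% over the spiked replicates; LOD/LOQ from the
    matrix curve by the residual-SD method (3.3 / 10 × s_y/x / slope).
    ``curves`` is (solvent, matrix-matched).
    """
    spiked_arr = np.asarray(spiked, dtype=float)
    if spiked_arr.size < 3:
        raise ValueError("need at least 3 replicates for RSD")
    if reference == 0:
        raise ValueError("zero reference response")
    out = {
        "recovery_pct": 100.0 * float(spiked_arr.mean()) / reference,
        "rsd_pct": 100.0 * float(spiked_arr.std(ddof=1)) / float(spiked_arr.mean()),
    }
    if curves is not None:
        solvent, matrix = curves
        if solvent.slope == 0 or matrix.slope == 0:
            raise ValueError("zero calibration slope")
        out["matrix_effect_pct"] = 100.0 * (matrix.slope / solvent.slope - 1.0)
        out["lod"] = matrix.lod
        out["loq"] = matrix.loq
    return out


# ---------------------------------------------------------------------------
# suspect screening


def match_msms(
    experimental: Spectrum,
    reference: Spectrum | list[float],
    tol_mda: float = 5.0,
) -> dict:
    """Fragment matching between an experimental and a reference spectrum.

    With reference intensities available the similarity is the cosine of
    the square-root-transformed intensity vectors over m/z-matched
    fragment pairs (unmatched peaks contribute zeros).  When the
    reference is a bare fragment list the pass criterion is at least
    three matched fragments; no similarity is reported.
    """
    exp_mzs = np.asarray(experimental.mzs, dtype=float)
    if exp_mzs.size == 0:
        raise ValueError("empty experimental spectrum")
    tol = tol_mda * 1e-3
    if isinstance(reference, Spectrum):
        ref_mzs = np.asarray(reference.mzs, dtype=float)
        ref_ints = np.asarray(reference.intensities, dtype=float)
        has_intensities = True
    else:
        ref_mzs = np.asarray(reference, dtype=float)
        ref_ints = np.ones_like(ref_mzs)
        has_intensities = False
    if ref_mzs.size == 0:
        raise ValueError("empty reference spectrum")
    matched: list[float] = []
    a = np.sqrt(np.asarray(experimental.intensities, dtype=float))
    b = np.sqrt(ref_ints)
    num = 0.0
    used = np.zeros(ref_mzs.size, dtype=bool)
    for i, mz in enumerate(exp_mzs):
        deltas = np.abs(ref_mzs - mz)
        deltas[used] = np.inf
        j = int(np.argmin(deltas))
        if deltas[j] <= tol:
            used[j] = True
            matched.append(float(ref_mzs[j]))
            num += a[i] * b[j]
    den = float(np.linalg.norm(a) * np.linalg.norm(b))
    similarity = num / den if den > 0 else 0.0
    result = {
        "similarity": similarity if has_intensities else None,
        "n_matched": len(matched),
        "matched": matched,
    }
    if not has_intensities:
        result["passes"] = len(matched) >= MIN_MATCHED_FRAGMENTS
    else:
        result["passes"] = similarity >= SIMILARITY_MIN
    return result


def assign_confidence(
    *,
    has_reference_standard: bool = False,
    formula_assigned: bool = False,
    rt_ok: bool = False,
    library_similarity: float | None = None,
    n_matched_fragments: int = 0,
    library_has_intensities: bool = True,
    insilico_evidence: bool = False,
    similarity_min: float = SIMILARITY_MIN,
    min_fragments: int = MIN_MATCHED_FRAGMENTS,
) -> str:
    """Identification-confidence ladder (1, 2a, 3, 4, 5).

    1: confirmed by reference standard (rt + MS/MS); 2a: library MS/MS
    match (similarity ≥ 0.7, or ≥3 matched fragments when the library
    spectrum lacks intensities) plus formula and retention-time
    plausibility; 3: tentative candidate supported by in-silico/fragment
    evidence only; 4: unequivocal molecular formula; 5: exact mass of
    interest only.  Ties resolve to the weaker (higher-numbered) level.
    """
    if has_reference_standard:
        return "1"
    library_pass = False
    if library_similarity is not None:
        library_pass = library_similarity >= similarity_min
    elif not library_has_intensities:
        library_pass = n_matched_fragments >= min_fragments
    if library_pass and formula_assigned and rt_ok:
        return "2a"
    if formula_assigned and (insilico_evidence or n_matched_fragments > 0):
        return "3"
    if formula_assigned:
        return "4"
    return "5"


def screen_suspects(
    run: Run,
    suspects: list[SuspectEntry],
    rt_window: float = RT_WINDOW_SUSPECT,
    mass_tol_mda: float = MASS_TOL_MDA,
    msigma_max: float = MSIGMA_MAX,
    min_intensity: float = MIN_INTENSITY,
    min_area: float = MIN_AREA,
    resolve: bool = True,
) -> list[Detection]:
    """Suspect screening with the full threshold chain.

    Per suspect: an EIC at the theoretical [M−H]⁻ m/z is extracted, peaks
    failing the intensity/area/mass-accuracy/isotopic-fit thresholds are
    dropped, survivors are checked against the predicted retention time
    (|Δt_R| below ``rt_window``) and evaluated against the suspect's
    expected fragments or library spectrum; the confidence level is then
    assigned from the accumulated evidence.  With ``resolve`` (default),
    peaks claimed by several isomeric suspects are assigned to the one
    with the strongest fragment evidence (:func:`resolve_isomers`).
    """
    detections: list[Detection] = []
    for suspect in suspects:
        theoretical_mz = suspect.precursor_mz
        eic = extract_eic(run, theoretical_mz, mass_tol_mda)
        theo_pattern = ion_isotope_pattern(suspect.formula)
        for peak in detect_peaks(eic):
            if not peak.height > min_intensity:
                continue
            if not peak.area > min_area:
                continue
            measured = _measured_mz(run, peak, theoretical_mz, mass_tol_mda)
            if measured is None:
                continue
            err = mass_error(measured, theoretical_mz)
            if abs(err.mda) >= mass_tol_mda:
                continue
            measured_pattern = measured_pattern_for_peak(
                run, peak, theo_pattern, mass_tol_mda
            )
            if measured_pattern is None:
                continue
            msigma, _ = isotopic_fit(measured_pattern, theo_pattern)
            if msigma > msigma_max:
                continue
            rt_err = None
            rt_ok = True
            if suspect.rt_predicted is not None:
                rt_err = peak.rt_apex - suspect.rt_predicted
                if not abs(rt_err) < rt_window:
                    continue
            similarity = None
            matched: list[float] = []
            n_matched = 0
            library_has_intensities = True
            try:
                msms = msms_for_peak(run, peak, theoretical_mz)
            except ValueError:
                msms = None
            if msms is not None and msms.mzs.size:
                if suspect.library_spectrum is not None:
                    result = match_msms(msms, suspect.library_spectrum, mass_tol_mda)
                    similarity = result["similarity"]
                    matched = result["matched"]
                    n_matched = result["n_matched"]
                elif suspect.expected_fragments:
                    result = match_msms(msms, suspect.expected_fragments, mass_tol_mda)
                    matched = result["matched"]
                    n_matched = result["n_matched"]
                    library_has_intensities = False
            level = assign_confidence(
                formula_assigned=True,
                rt_ok=rt_ok,
                library_similarity=similarity,
                n_matched_fragments=n_matched,
                library_has_intensities=library_has_intensities,
                insilico_evidence=n_matched > 0,
            )
            n_expected = (
                len(suspect.library_spectrum.mzs)
                if suspect.library_spectrum is not None
                else len(suspect.expected_fragments) or None
            )
            detections.append(
                Detection(
                    name=suspect.name,
                    peak=peak,
                    mass_error=err,
                    isotopic_fit=msigma,
                    matched_fragments=matched,
                    rt_error=rt_err,
                    similarity=similarity,
                    confidence_level=level,
                    formula=suspect.formula,
                    measured_mz=measured,
                    n_expected_fragments=n_expected,
                )
            )
    if resolve:
        detections = resolve_isomers(detections)
    return detections


def resolve_isomers(detections: list[Detection]) -> list[Detection]:
    """Assign each chromatographic peak to its best-supported isomer.

    Suspects sharing the same molecular formula produce a detection per
    peak each; for every (formula, peak) group only the detection with
    the strongest fragment evidence is kept — more matched fragments
    first, then the larger matched fraction of the expected fragment
    list (the diagnostic-fragment rule: an isomer whose characteristic
    fragment is absent loses to one whose list is fully explained).
    Exact ties keep all contenders.
    """
    groups: dict[tuple, list[Detection]] = {}
    for d in detections:
        key = (str(d.formula), round(d.peak.rt_apex, 2))
        groups.setdefault(key, []).append(d)
    kept: list[Detection] = []
    for group in groups.values():
        def strength(d: Detection) -> tuple[float, float]:
            n = len(d.matched_fragments)
            frac = n / d.n_expected_fragments if d.n_expected_fragments else 0.0
            return (n, frac)

        best = max(strength(d) for d in group)
        kept.extend(d for d in group if strength(d) == best)
    kept.sort(key=lambda d: (d.peak.rt_apex, d.name))
    return kept


# ---------------------------------------------------------------------------
# list I/O


def _split_floats(cell) -> list[float]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return []
    return [float(tok) for tok in str(cell).split(";") if tok.strip()]


def load_target_list(path: str) -> list[TargetEntry]:
    """CSV columns: name, formula, rt_expected, [precursor_mz], qualifiers."""
    frame = pd.read_csv(path)
    entries = []
    for _, row in frame.iterrows():
        precursor = row.get("precursor_mz")
        entries.append(
            TargetEntry(
                name=row["name"],
                formula=parse_formula(row["formula"]),
                rt_expected=float(row["rt_expected"]),
                precursor_mz=None if pd.isna(precursor) else float(precursor),
                qualifier_ions=_split_floats(row.get("qualifiers")),
            )
        )
    return entries


def load_suspect_list(path: str) -> list[SuspectEntry]:
    """CSV columns: name, formula, [rt_predicted], [fragments] (semicolon-sep)."""
    frame = pd.read_csv(path)
    entries = []
    for _, row in frame.iterrows():
        rt_pred = row.get("rt_predicted")
        entries.append(
            SuspectEntry(
                name=row["name"],
                formula=parse_formula(row["formula"]),
                rt_predicted=None if pd.isna(rt_pred) else float(rt_pred),
                expected_fragments=_split_floats(row.get("fragments")),
            )
        )
    return entries


def load_library(path: str) -> dict[str, Spectrum]:
    """Load an MSP or MGF spectral library, keyed by compound name.

    Parsing is delegated to matchms; spectra are converted to the local
    fragment-spectrum type (rt 0, high-energy channel).
    """
    from matchms.importing import load_from_mgf, load_from_msp

    loader = load_from_msp if path.lower().endswith(".msp") else load_from_mgf
    library: dict[str, Spectrum] = {}
    for record in loader(path):
        if record is None:
            continue
        name = record.get("compound_name") or record.get("title") or f"spectrum_{len(library)}"
        library[str(name)] = Spectrum(
            rt=0.0,
            channel="high",
            mzs=np.asarray(record.peaks.mz, dtype=float),
            intensities=np.asarray(record.peaks.intensities, dtype=float),
        )
    return library


def detections_to_frame(detections: list[Detection]) -> pd.DataFrame:
    """Detection report mirroring the suspect-table columns."""
    rows = []
    for d in detections:
        rows.append(
            {
                "compound": d.name,
                "formula": str(d.formula) if d.formula else "",
                "measured_mz": d.measured_mz,
                "mass_error_mda": d.mass_error.mda if d.mass_error else None,
                "rt_apex_min": d.peak.rt_apex,
                "rt_error_min": d.rt_error,
                "isotopic_fit": d.isotopic_fit,
                "height": d.peak.height,
                "area": d.peak.area,
                "similarity": d.similarity,
                "n_matched_fragments": len(d.matched_fragments),
                "confidence_level": d.confidence_level,
            }
        )
    return pd.DataFrame(rows)
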