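"""Synthetic study generator with known ground truth.

Emulates the structure of a two-country honey-origin study: a 51-sample ×
408-feature intensity table (plus procedural blank and pooled-QC rows), a
handful of genuinely discriminative features buried under strong shared
nuisance variance, raw two-channel DIA runs containing Gaussian
chromatographic peaks that carry correct [M−H]⁻ isotope patterns and
co-eluting fragment ions, and five-level calibration sets.

The feature table is built on the log-intensity scale: every feature has
a log-normal baseline; marker features receive a between-class mean shift
expressed in units of the within-class standard deviation; non-marker
features additionally load on a shared rank-1 nuisance factor whose
variance dwarfs the class signal.  Under autoscaling or Pareto scaling
that nuisance dominates the leading PLS components, while Vast scaling
down-weights the high-CV nuisance features and recovers the class
structure — the behaviour the pipeline is designed to exhibit.

All outputs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import MolecularFormula, ion_isotope_pattern, parse_formula
from .msdata import Run, Spectrum
from .nontarget import ROLE_BLANK, ROLE_QC, ROLE_SAMPLE, FeatureTable, make_feature_id

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "SimCompound",
    "simulate_feature_table",
    "simulate_run",
    "simulate_calibration",
    "CALIBRATION_LEVELS",
]

#: calibration levels in mg/L
CALIBRATION_LEVELS = (0.25, 0.5, 1.0, 2.0, 5.0)


@dataclass
class SimulationDesign:
    """Study conditions for the synthetic two-class feature table.

    Defaults mirror the emulated study: 51 honey samples (26 + 25 per
    origin), 408 aligned mass features, 10 discriminative markers with a
    between-class shift of 3 within-class standard deviations, one
    procedural blank and 5 pooled-QC injections.
    """

    n_per_class: tuple[int, int] = (26, 25)
    n_features: int = 408
    n_markers: int = 10
    effect: float = 3.0  # between-class mean shift / within-class sd
    confound_sd: float = 6.0  # nuisance-factor loading scale, × within-sd
    n_blanks: int = 1
    n_qc: int = 5
    n_contaminants: int = 15  # blank-borne features
    n_unstable: int = 10  # high-QC-RSD features
    seed: int = 0
    class_names: tuple[str, str] = ("Greek", "Polish")
    within_sd: float = 0.25  # log-scale within-class sd

    def __post_init__(self) -> None:
        if self.n_markers > self.n_features:
            raise ValueError("n_markers cannot exceed n_features")
        if self.effect < 0:
            raise ValueError("effect must be non-negative")
        if min(self.n_per_class) < 2:
            raise ValueError("need at least 2 samples per class")
        if self.n_markers + self.n_contaminants + self.n_unstable > self.n_features:
            raise ValueError("marker/contaminant/unstable sets exceed feature count")


@dataclass
class GroundTruth:
    marker_ids: list[str] = field(default_factory=list)
    contaminant_ids: list[str] = field(default_factory=list)
    unstable_ids: list[str] = field(default_factory=list)
    class_assignments: dict = field(default_factory=dict)
    spiked_compounds: list = field(default_factory=list)


def simulate_feature_table(design: SimulationDesign) -> tuple[FeatureTable, GroundTruth]:
    """Generate a class-structured feature table with known markers."""
    rng = np.random.default_rng(design.seed)
    n1, n2 = design.n_per_class
    n_samples = n1 + n2
    I = design.n_features
    sw = design.within_sd

    mz = np.sort(rng.uniform(60.0, 950.0, I))
    rt = np.round(rng.uniform(0.5, 11.5, I), 2)
    feature_ids = [make_feature_id(m, t) for m, t in zip(mz, rt)]
    # regenerate any collisions after rounding
    while len(set(feature_ids)) < I:
        seen: set[str] = set()
        for j, fid in enumerate(feature_ids):
            if fid in seen:
                mz[j] = rng.uniform(60.0, 950.0)
                feature_ids[j] = make_feature_id(mz[j], rt[j])
            seen.add(feature_ids[j])

    special = rng.choice(
        I, size=design.n_markers + design.n_contaminants + design.n_unstable, replace=False
    )
    markers = special[: design.n_markers]
    contaminants = special[design.n_markers : design.n_markers + design.n_contaminants]
    unstable = special[design.n_markers + design.n_contaminants :]

    mu = rng.normal(np.log(1e4), 1.0, I)  # log-scale baselines
    class_sign = np.concatenate([np.full(n1, -1.0), np.full(n2, +1.0)])
    # shared per-sample nuisance factor: bounded (batch/drift-like), unit
    # variance, so held-out samples never sit far outside the training range
    nuisance_score = rng.uniform(-math.sqrt(3.0), math.sqrt(3.0), n_samples)
    loading = np.zeros(I)
    non_marker = np.setdiff1d(np.arange(I), markers)
    loading[non_marker] = design.confound_sd * sw * rng.uniform(0.5, 1.5, non_marker.size)

    log_x = (
        mu[None, :]
        + nuisance_score[:, None] * loading[None, :]
        + rng.normal(0.0, sw, (n_samples, I))
    )
    log_x[:, markers] += (
        class_sign[:, None] * (design.effect * sw / 2.0) * np.ones((1, markers.size))
    )
    samples = np.exp(log_x)

    grand = np.exp(mu)
    blank = np.zeros((design.n_blanks, I))
    if design.n_blanks:
        blank += grand[None, :] * 0.002 * rng.lognormal(0.0, 0.3, (design.n_blanks, I))
        blank[:, contaminants] = grand[None, contaminants] * rng.lognormal(
            0.0, 0.1, (design.n_blanks, contaminants.size)
        )
    qc = grand[None, :] * rng.lognormal(0.0, 0.05, (design.n_qc, I))
    if design.n_qc:
        qc[:, unstable] = grand[None, unstable] * rng.lognormal(
            0.0, 1.0, (design.n_qc, unstable.size)
        )

    sample_ids = (
        [f"{design.class_names[0]}_{i + 1:02d}" for i in range(n1)]
        + [f"{design.class_names[1]}_{i + 1:02d}" for i in range(n2)]
        + [f"blank_{i + 1}" for i in range(design.n_blanks)]
        + [f"QC_{i + 1}" for i in range(design.n_qc)]
    )
    matrix = pd.DataFrame(
        np.vstack([samples, blank, qc]), index=sample_ids, columns=feature_ids
    )
    roles = pd.Series(
        [ROLE_SAMPLE] * n_samples + [ROLE_BLANK] * design.n_blanks + [ROLE_QC] * design.n_qc,
        index=sample_ids,
    )
    labels = (
        [design.class_names[0]] * n1
        + [design.class_names[1]] * n2
        + [None] * (design.n_blanks + design.n_qc)
    )
    classes = pd.Series(labels, index=sample_ids, dtype=object)
    table = FeatureTable(matrix=matrix, roles=roles, classes=classes)
    truth = GroundTruth(
        marker_ids=[feature_ids[j] for j in markers],
        contaminant_ids=[feature_ids[j] for j in contaminants],
        unstable_ids=[feature_ids[j] for j in unstable],
        class_assignments={
            sid: lab for sid, lab in zip(sample_ids[:n_samples], labels[:n_samples])
        },
    )
    return table, truth


@dataclass
class SimCompound:
    """Ground-truth spike for a simulated DIA run."""

    name: str
    formula: MolecularFormula | str
    rt: float  # apex, minutes
    height: float  # apex intensity of the monoisotopic ion, counts
    fragments: list[float] = field(default_factory=list)
    fragment_rel: float = 0.4  # fragment intensity relative to precursor height

    def __post_init__(self) -> None:
        if isinstance(self.formula, str):
            self.formula = parse_formula(self.formula)
        if self.height <= 0:
            raise ValueError("height must be positive")


def simulate_run(
    compounds: list[SimCompound],
    noise: float = 0.0,
    seed: int = 0,
    rt_span: tuple[float, float] = (0.0, 6.0),
    scan_rate: float = 2.0,  # Hz, per channel
    peak_sigma: float = 0.05,  # min, Gaussian elution sd
    mz_range: tuple[float, float] = (50.0, 1000.0),
    sample_id: str = "synthetic",
    sample_role: str = "sample",
    class_label: str | None = None,
) -> Run:
    """Build a two-channel DIA run from ground-truth compound spikes.

    The low-energy channel carries each compound's [M−H]⁻ isotope pattern
    under a Gaussian elution profile; the high-energy channel carries the
    declared fragment ions co-eluting with the precursor.  ``noise`` adds
    a random centroid floor of roughly that intensity to every scan.
    """
    for c in compounds:
        if not rt_span[0] <= c.rt <= rt_span[1]:
            raise ValueError(f"{c.name}: rt {c.rt} outside the gradient span")
    keys = {(round(float(c.rt), 3), str(c.formula)) for c in compounds}
    if len(keys) < len(compounds):
        raise ValueError("overlapping identical formula+rt ground-truth entries")
    rng = np.random.default_rng(seed)
    dt = 1.0 / (scan_rate * 60.0)  # minutes between scans, per channel
    times = np.arange(rt_span[0], rt_span[1] + dt / 2, dt)
    patterns = [ion_isotope_pattern(c.formula) for c in compounds]

    low, high = [], []
    for k, t in enumerate(times):
        mz_lo: list[float] = []
        int_lo: list[float] = []
        mz_hi: list[float] = []
        int_hi: list[float] = []
        for c, pattern in zip(compounds, patterns):
            g = c.height * np.exp(-0.5 * ((t - c.rt) / peak_sigma) ** 2)
            if g < 0.5:
                continue
            for mass, ab in pattern.peaks:
                mz_lo.append(mass)
                int_lo.append(g * ab)
            mz_hi.append(pattern.peaks[0][0])
            int_hi.append(0.2 * g)
            for frag in c.fragments:
                mz_hi.append(frag)
                int_hi.append(c.fragment_rel * g)
        if noise > 0:
            for mzs, ints in ((mz_lo, int_lo), (mz_hi, int_hi)):
                n_noise = rng.poisson(5)
                mzs.extend(rng.uniform(*mz_range, n_noise))
                ints.extend(rng.exponential(noise, n_noise))
        low.append(_centroid_spectrum(t, "low", mz_lo, int_lo))
        high.append(
            _centroid_spectrum(t + dt / 2.0, "high", mz_hi, int_hi)
        )
    return Run(
        low=low,
        high=high,
        sample_id=sample_id,
        sample_role=sample_role,
        class_label=class_label,
        mz_range=mz_range,
    )


def _centroid_spectrum(rt, channel, mzs, ints) -> Spectrum:
    mz_arr = np.asarray(mzs, dtype=float)
    int_arr = np.asarray(ints, dtype=float)
    order = np.argsort(mz_arr)
    mz_arr, int_arr = mz_arr[order], int_arr[order]
    # merge exact duplicates so the centroid axis stays strictly increasing
    if mz_arr.size:
        uniq, inverse = np.unique(mz_arr, return_inverse=True)
        merged = np.zeros_like(uniq)
        np.add.at(merged, inverse, int_arr)
        mz_arr, int_arr = uniq, merged
    return Spectrum(rt=float(rt), channel=channel, mzs=mz_arr, intensities=int_arr)


def simulate_calibration(
    slope: float,
    intercept: float = 0.0,
    noise_cv: float = 0.02,
    levels: tuple[float, ...] = CALIBRATION_LEVELS,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Level/response pairs with multiplicative log-normal noise."""
    if slope <= 0:
        raise ValueError("slope must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if not levels:
        raise ValueError("empty level list")
    rng = np.random.default_rng(seed)
    pairs = []
    for c in levels:
        response = slope * c + intercept
        if noise_cv > 0:
            response *= rng.lognormal(0.0, noise_cv)
        pairs.append((float(c), float(response)))
    return pairs
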