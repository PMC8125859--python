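"""Non-target feature-table handling and candidate annotation.

A feature table is a samples × features intensity matrix whose columns
are ``"m/z_tR"`` identifiers (m/z to 4 d.p., retention time in minutes to
2 d.p.), with per-sample roles (sample / blank / QC) and origin class
labels.  Features traceable to the procedural blank are removed by a
transparent fold-change rule, unstable features by their pooled-QC RSD,
and prioritized masses are annotated against a local candidate list of
natural products retrieved within a 2 mDa window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import (
    MolecularFormula,
    ion_isotope_pattern,
    mass_error,
    monoisotopic_mass,
    parse_formula,
    pseudomolecular_mz,
)
from .msdata import Spectrum
from .screening import Detection, assign_confidence, match_msms

__all__ = [
    "FeatureTable",
    "CandidateRecord",
    "make_feature_id",
    "parse_feature_id",
    "blank_subtract",
    "qc_filter",
    "candidate_lookup",
    "annotate_feature",
    "load_candidate_db",
]

ROLE_SAMPLE = "sample"
ROLE_BLANK = "blank"
ROLE_QC = "QC"


def make_feature_id(mz: float, rt: float) -> str:
    """Underscore-joined rounded values, e.g. ``"253.0512_9.66"``."""
    return f"{mz:.4f}_{rt:.2f}"


def parse_feature_id(feature_id: str) -> tuple[float, float]:
    try:
        mz_text, rt_text = feature_id.split("_")
        return float(mz_text), float(rt_text)
    except ValueError as exc:
        raise ValueError(f"unparseable feature id {feature_id!r}") from exc


@dataclass
class FeatureTable:
    """Samples × features intensities with roles and class labels."""

    matrix: pd.DataFrame  # index = sample ids, columns = feature ids
    roles: pd.Series  # per sample: sample | blank | QC
    classes: pd.Series  # per sample: origin label (may be NA for blanks/QCs)

    def __post_init__(self) -> None:
        if self.matrix.columns.duplicated().any():
            raise ValueError("duplicate feature ids")
        if not self.matrix.index.equals(self.roles.index) or not self.matrix.index.equals(
            self.classes.index
        ):
            raise ValueError("roles/classes must be indexed by the sample ids")
        if (self.matrix.values < 0).any():
            raise ValueError("negative intensities")
        unlabeled = (self.roles == ROLE_SAMPLE) & self.classes.isna()
        if unlabeled.any():
            raise ValueError(
                f"samples without class label: {list(self.matrix.index[unlabeled])}"
            )

    @property
    def sample_matrix(self) -> pd.DataFrame:
        return self.matrix.loc[self.roles == ROLE_SAMPLE]

    @property
    def sample_classes(self) -> pd.Series:
        return self.classes.loc[self.roles == ROLE_SAMPLE]

    def to_csv(self, path: str) -> None:
        out = self.matrix.copy()
        out.insert(0, "class", self.classes)
        out.insert(0, "role", self.roles)
        out.to_csv(path, index_label="sample")

    @classmethod
    def from_csv(cls, path: str) -> "FeatureTable":
        frame = pd.read_csv(path, index_col="sample")
        roles = frame.pop("role")
        classes = frame.pop("class")
        return cls(matrix=frame, roles=roles, classes=classes)


@dataclass
class CandidateRecord:
    """One entry of a local natural-products candidate list."""

    name: str
    formula: MolecularFormula
    monoisotopic: float
    rt_predicted: float | None = None
    source: str = ""
    fragments: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = monoisotopic_mass(self.formula)
        if abs(self.monoisotopic - expected) > 1e-3:
            raise ValueError(
                f"{self.name}: stated mass {self.monoisotopic} inconsistent with "
                f"{self.formula} ({expected:.5f})"
            )

    @property
    def ion_mz(self) -> float:
        return pseudomolecular_mz(self.formula)


def blank_subtract(table: FeatureTable, fold: float = 5.0) -> FeatureTable:
    """Remove features attributable to the procedural blank.

    A feature is retained iff mean(sample intensity) ≥ fold × mean(blank
    intensity).  Blank rows are dropped from the output.  Without any
    blank the table passes through unchanged with a warning.
    """
    blanks = table.matrix.loc[table.roles == ROLE_BLANK]
    if blanks.empty:
        warnings.warn("no procedural blank present; table unchanged", stacklevel=2)
        return table
    sample_mean = table.sample_matrix.mean(axis=0)
    blank_mean = blanks.mean(axis=0)
    keep = sample_mean >= fold * blank_mean
    keep_rows = table.roles != ROLE_BLANK
    return FeatureTable(
        matrix=table.matrix.loc[keep_rows, keep[keep].index],
        roles=table.roles.loc[keep_rows],
        classes=table.classes.loc[keep_rows],
    )


def qc_filter(table: FeatureTable, rsd_max: float = 30.0) -> FeatureTable:
    """Drop features whose pooled-QC replicate RSD% exceeds ``rsd_max``."""
    qcs = table.matrix.loc[table.roles == ROLE_QC]
    if len(qcs) < 3:
        warnings.warn("fewer than 3 QC injections; table unchanged", stacklevel=2)
        return table
    mean = qcs.mean(axis=0)
    sd = qcs.std(axis=0, ddof=1)
    rsd = 100.0 * sd / mean.replace(0, np.nan)
    keep = ~(rsd > rsd_max)
    return FeatureTable(
        matrix=table.matrix.loc[:, keep[keep].index],
        roles=table.roles,
        classes=table.classes,
    )


def candidate_lookup(
    mz: float, db: list[CandidateRecord], tol_mda: float = 2.0
) -> list[tuple[CandidateRecord, float]]:
    """Candidates whose [M−H]⁻ m/z lies within ±tol of the query.

    Returns (record, signed mDa error) pairs ordered by |error|; ties
    break on the candidate name.
    """
    if not db:
        raise ValueError("empty candidate list")
    hits = []
    for record in db:
        err = (mz - record.ion_mz) * 1e3
        if abs(err) <= tol_mda:
            hits.append((record, err))
    hits.sort(key=lambda pair: (abs(pair[1]), pair[0].name))
    return hits


def annotate_feature(
    feature_id: str,
    db: list[CandidateRecord],
    msms: Spectrum | None = None,
    library_spectrum: Spectrum | None = None,
    measured_pattern=None,
    tol_mda: float = 2.0,
    rt_window: float = 1.8,
    msigma_max: float = 50.0,
    peak=None,
) -> Detection | None:
    """Annotate one prioritized mass feature against the candidate list.

    Pipeline: parse the id into (m/z, t_R); retrieve candidates within the
    mass window; drop candidates whose predicted retention time misses
    the window; check the isotopic fit when a measured pattern is given;
    score fragments (explained fraction of the experimental spectrum
    against the candidate's fragment list, library cosine when a library
    spectrum exists); assign the identification confidence level.
    Returns None when no candidate survives.
    """
    from .chem import isotopic_fit  # local import to avoid cycle noise
    from .msdata import ChromPeak

    mz, rt = parse_feature_id(feature_id)
    survivors = []
    for record, err in candidate_lookup(mz, db, tol_mda):
        if record.rt_predicted is not None and abs(rt - record.rt_predicted) >= rt_window:
            continue
        msigma = None
        if measured_pattern is not None:
            theo = ion_isotope_pattern(record.formula)
            msigma, _ = isotopic_fit(measured_pattern, theo)
            if msigma > msigma_max:
                continue
        survivors.append((record, err, msigma))
    if not survivors:
        return None
    record, err, msigma = survivors[0]
    similarity = None
    matched: list[float] = []
    n_matched = 0
    if msms is not None and len(msms.mzs):
        if library_spectrum is not None:
            result = match_msms(msms, library_spectrum, tol_mda)
            similarity = result["similarity"]
            matched, n_matched = result["matched"], result["n_matched"]
        elif record.fragments:
            result = match_msms(msms, record.fragments, tol_mda)
            matched, n_matched = result["matched"], result["n_matched"]
    # candidate fragment lists are in-silico evidence (level 3 at best);
    # only a genuine library spectrum can raise the annotation to 2a
    level = assign_confidence(
        formula_assigned=True,
        rt_ok=True,
        library_similarity=similarity,
        n_matched_fragments=n_matched,
        library_has_intensities=True,
        insilico_evidence=n_matched > 0,
    )
    if peak is None:
        peak = ChromPeak(rt_apex=rt, height=1.0, area=1.0, snr=0.0, bounds=(rt - 0.05, rt + 0.05))
    return Detection(
        name=record.name,
        peak=peak,
        mass_error=mass_error(mz, record.ion_mz),
        isotopic_fit=msigma,
        matched_fragments=matched,
        rt_error=None if record.rt_predicted is None else rt - record.rt_predicted,
        similarity=similarity,
        confidence_level=level,
        formula=record.formula,
        measured_mz=mz,
    )


def load_candidate_db(path: str) -> list[CandidateRecord]:
    """CSV columns: name, formula, monoisotopic_mass, [rt_predicted], [source], [fragments]."""
    frame = pd.read_csv(path)
    records = []
    for _, row in frame.iterrows():
        rt_pred = row.get("rt_predicted")
        fragments_cell = row.get("fragments")
        fragments = (
            []
            if fragments_cell is None or pd.isna(fragments_cell)
            else [float(tok) for tok in str(fragments_cell).split(";") if tok.strip()]
        )
        records.append(
            CandidateRecord(
                name=row["name"],
                formula=parse_formula(row["formula"]),
                monoisotopic=float(row["monoisotopic_mass"]),
                rt_predicted=None if pd.isna(rt_pred) else float(rt_pred),
                source=str(row.get("source", "")),
                fragments=fragments,
            )
        )
    return records
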