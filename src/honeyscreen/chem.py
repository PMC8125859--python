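"""Molecular-formula arithmetic for negative-mode HRMS screening.

Monoisotopic masses, [M−H]⁻ pseudomolecular ions, mass errors, theoretical
isotope patterns and pattern-fit scores.  All masses are in daltons (Da),
ion positions in m/z for singly charged ions.

The isotope mass/abundance table is shipped as a plain-text resource
(``data/isotopes.tsv``); elements outside that table are rejected rather
than silently approximated.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "MolecularFormula",
    "IsotopePattern",
    "MassError",
    "parse_formula",
    "monoisotopic_mass",
    "pseudomolecular_mz",
    "ion_isotope_pattern",
    "mass_error",
    "isotope_pattern",
    "isotopic_fit",
]

ELECTRON_MASS = 0.000548580  # Da
#: mass of a proton = H-atom mass − electron mass
PROTON_MASS = 1.007825032 - ELECTRON_MASS


def _load_isotopes() -> dict[str, list[tuple[float, float]]]:
    table: dict[str, list[tuple[float, float]]] = {}
    text = resources.files("honeyscreen").joinpath("data/isotopes.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        element, mass, abundance = line.split("\t")
        table.setdefault(element, []).append((float(mass), float(abundance)))
    for isotopes in table.values():
        isotopes.sort()  # lightest first
    return table


ISOTOPES: dict[str, list[tuple[float, float]]] = _load_isotopes()
SUPPORTED_ELEMENTS = frozenset(ISOTOPES)

#: monoisotopic (lightest-isotope) atomic masses
MONOISOTOPIC: dict[str, float] = {el: iso[0][0] for el, iso in ISOTOPES.items()}


class FormulaError(ValueError):
    """Raised for malformed or unsupported molecular formulas."""


@dataclass(frozen=True)
class MolecularFormula:
    """Element → count map, e.g. ``{"C": 15, "H": 20, "O": 4}``.

    Counts are strictly positive and elements must belong to the shipped
    isotope table.  ``str()`` renders the canonical Hill-order text form
    (C first, H second, remaining elements alphabetically; purely
    alphabetical when no carbon is present).
    """

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for element, count in self.counts.items():
            if element not in SUPPORTED_ELEMENTS:
                raise FormulaError(f"unsupported element {element!r}")
            if not isinstance(count, int) or count < 1:
                raise FormulaError(f"count for {element} must be a positive integer")

    def __str__(self) -> str:
        return "".join(
            f"{el}{self.counts[el] if self.counts[el] != 1 else ''}"
            for el in self._hill_order()
        )

    def _hill_order(self) -> list[str]:
        elements = sorted(self.counts)
        if "C" in self.counts:
            head = ["C"] + (["H"] if "H" in self.counts else [])
            return head + [e for e in elements if e not in ("C", "H")]
        return elements

    def merge(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for element, count in other.counts.items():
            merged[element] = merged.get(element, 0) + count
        return MolecularFormula(merged)

    def remove(self, element: str, n: int = 1) -> "MolecularFormula":
        if self.counts.get(element, 0) < n:
            raise FormulaError(f"cannot remove {n} {element} from {self}")
        counts = dict(self.counts)
        counts[element] -= n
        if counts[element] == 0:
            del counts[element]
        return MolecularFormula(counts)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style formula string such as ``"C15H20O4"``."""
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        match = _TOKEN.match(text, pos)
        if match is None or match.start() != pos or not match.group(1):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        element, digits = match.groups()
        if element not in SUPPORTED_ELEMENTS:
            # a two-letter guess may shadow a valid one-letter element (e.g. "Hx")
            if len(element) == 2 and element[0] in SUPPORTED_ELEMENTS:
                raise FormulaError(f"unknown element {element!r} in {text!r}")
            raise FormulaError(f"unknown element {element!r} in {text!r}")
        count = int(digits) if digits else 1
        if count < 1:
            raise FormulaError(f"zero count for {element} in {text!r}")
        counts[element] = counts.get(element, 0) + count
        pos = match.end()
    return MolecularFormula(counts)


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Sum of count × lightest-isotope mass over all elements (Da)."""
    return sum(count * MONOISOTOPIC[el] for el, count in f.counts.items())


#: supported adducts: id → (formula transform, charge-carrier mass shift)
#: [M−H]⁻: remove one H atom, add one electron.
_ADDUCT_ALIASES = {"[M-H]-", "[M−H]−", "[M−H]-", "[M-H]−"}


def pseudomolecular_mz(f: MolecularFormula, adduct: str = "[M-H]-") -> float:
    """m/z of the pseudomolecular ion; only [M−H]⁻ is supported.

    m/z = neutral monoisotopic mass − H-atom mass + electron mass.  The
    electron mass matters at the fourth decimal and is included; rounding
    is left to presentation.
    """
    if adduct not in _ADDUCT_ALIASES:
        raise ValueError(f"unknown adduct {adduct!r}")
    return monoisotopic_mass(f) - MONOISOTOPIC["H"] + ELECTRON_MASS


@dataclass(frozen=True)
class MassError:
    """Signed mass error, convention measured − theoretical."""

    mda: float
    ppm: float


def mass_error(measured: float, theoretical: float) -> MassError:
    if measured <= 0 or theoretical <= 0:
        raise ValueError("masses must be positive")
    mda = (measured - theoretical) * 1e3
    ppm = mda / theoretical * 1e3
    return MassError(mda=mda, ppm=ppm)


@dataclass(frozen=True)
class IsotopePattern:
    """Ordered (mass Da, relative abundance) peaks; base peak abundance = 1."""

    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        masses = [m for m, _ in self.peaks]
        if masses != sorted(masses) or len(set(masses)) != len(masses):
            raise ValueError("pattern masses must be strictly increasing")
        for _, a in self.peaks:
            if not 0 < a <= 1:
                raise ValueError("abundances must lie in (0, 1]")

    @property
    def masses(self) -> list[float]:
        return [m for m, _ in self.peaks]

    @property
    def abundances(self) -> list[float]:
        return [a for _, a in self.peaks]


def _convolve(
    a: dict[int, tuple[float, float]], b: dict[int, tuple[float, float]]
) -> dict[int, tuple[float, float]]:
    # entries: nominal shift -> (probability, probability-weighted mass sum)
    out: dict[int, tuple[float, float]] = {}
    for s1, (p1, m1) in a.items():
        for s2, (p2, m2) in b.items():
            p = p1 * p2
            if p < 1e-12:
                continue
            shift = s1 + s2
            prev_p, prev_m = out.get(shift, (0.0, 0.0))
            # m1/p1 and m2/p2 are mean masses; weight their sum by p
            out[shift] = (prev_p + p, prev_m + p * (m1 / p1 + m2 / p2))
    return {s: (p, m) for s, (p, m) in out.items()}


def isotope_pattern(f: MolecularFormula, prune: float = 1e-4) -> IsotopePattern:
    """Theoretical isotope pattern by per-element polynomial convolution.

    Isotopologues are aggregated into nominal-mass-shift peaks (M, M+1,
    M+2, …) with abundance-weighted mean masses; peaks below ``prune``
    relative abundance (after base-peak normalisation) are removed.
    Equivalent to exhaustive isotopologue enumeration for small formulas.
    """
    if not f.counts:
        return IsotopePattern(peaks=())
    dist: dict[int, tuple[float, float]] = {0: (1.0, 0.0)}
    for element, count in f.counts.items():
        lightest = ISOTOPES[element][0][0]
        atom = {
            round(mass - lightest): (ab, ab * mass)
            for mass, ab in ISOTOPES[element]
        }
        # exponentiation by repeated convolution; counts are small
        for _ in range(count):
            dist = _convolve(dist, atom)
    base = max(p for p, _ in dist.values())
    peaks = []
    for shift in sorted(dist):
        p, msum = dist[shift]
        rel = p / base
        if rel >= prune:
            peaks.append((msum / p, rel))
    return IsotopePattern(peaks=tuple(peaks))


def ion_isotope_pattern(
    f: MolecularFormula, adduct: str = "[M-H]-", prune: float = 1e-4
) -> IsotopePattern:
    """Isotope pattern of the deprotonated ion, on the m/z axis.

    Computed for the ion formula (one H removed) with the electron mass
    added to every isotopologue mass, so it aligns with measured centroid
    m/z values.
    """
    if adduct not in _ADDUCT_ALIASES:
        raise ValueError(f"unknown adduct {adduct!r}")
    neutral = isotope_pattern(f.remove("H"), prune=prune)
    return IsotopePattern(
        peaks=tuple((m + ELECTRON_MASS, a) for m, a in neutral.peaks)
    )


def _shift_vectors(
    measured: IsotopePattern, theoretical: IsotopePattern
) -> tuple[list[float], list[float]]:
    """Align both patterns on nominal shifts from the theoretical base mass.

    Measured peaks are at absolute (extracted) positions, so a measured
    peak one nominal mass above the theoretical monoisotopic peak lands
    at shift +1; patterns with no common shift are orthogonal.
    """
    t0 = theoretical.peaks[0][0]
    m_by_shift = {round(m - t0): a for m, a in measured.peaks}
    t_by_shift = {round(m - t0): a for m, a in theoretical.peaks}
    shifts = sorted(set(m_by_shift) | set(t_by_shift))
    return (
        [m_by_shift.get(s, 0.0) for s in shifts],
        [t_by_shift.get(s, 0.0) for s in shifts],
    )


def isotopic_fit(
    measured: IsotopePattern, theoretical: IsotopePattern
) -> tuple[float, float]:
    """Goodness of isotope-pattern fit: ``(msigma_like, dot)``.

    ``dot`` is the cosine of the matched-abundance vectors in [0, 1].
    ``msigma_like`` is a declared surrogate for the vendor mSigma score:
    1000 × the RMS deviation of matched base-peak-normalised abundances
    (lower is better; expected peaks missing from one side count as
    zero-abundance matches).  Thresholds quoted against mSigma (≤ 50)
    apply to this surrogate.
    """
    if not measured.peaks or not theoretical.peaks:
        raise ValueError("patterns must contain at least one peak")
    mv, tv = _shift_vectors(measured, theoretical)
    diff2 = [(a - b) ** 2 for a, b in zip(mv, tv)]
    msigma_like = 1000.0 * math.sqrt(sum(diff2) / len(diff2))
    num = sum(a * b for a, b in zip(mv, tv))
    den = math.sqrt(sum(a * a for a in mv)) * math.sqrt(sum(b * b for b in tv))
    dot = num / den if den > 0 else 0.0
    return msigma_like, min(dot, 1.0)
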