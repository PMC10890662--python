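"""Molecular-formula arithmetic and exact-mass computation.

Gibberellins (GAs) are tetracyclic diterpene carboxylic acids.  Their
glucose conjugates (Glc-GAs) carry one glucosyl unit (net addition of
C6H10O5), and chemical derivatization with N,N-dimethylethylenediamine
(DMED) converts a free carboxyl into an amide (net +C4H12N2 -H2O).  The
heavy tag d4-DMED carries four deuteriums and shifts every derivatized ion
by 4 x (m(D) - m(H)) = +4.0251 Da, creating the light/heavy mass channels
used for peak-pair screening.

This module provides the formula container, the element masses, and the
handful of mass operations (protonation, cation m/z, delta application,
heavy-channel shift) everything downstream is built on.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping

__all__ = [
    "Formula",
    "FormulaDelta",
    "IsotopeTagPair",
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "parse_formula",
    "monoisotopic_mass",
    "apply_delta",
    "mz_protonated",
    "heavy_mz",
    "cation_mz",
    "GLUCOSYLATION",
    "DMED_AMIDATION",
    "DMED_TAG",
    "export_element_masses",
]

#: Monoisotopic masses (Da), CODATA/IUPAC values.  "D" is deuterium,
#: treated as a distinct element symbol so heavy-reagent formulas can be
#: written directly (e.g. C4H8D4N2 for d4-DMED).
MONOISOTOPIC_MASS: Dict[str, float] = {
    "H": 1.00782503207,
    "D": 2.01410177785,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "F": 18.99840322,
    "Cl": 34.96885268,
    "Br": 78.9183371,
    "I": 126.904473,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Si": 27.9769265325,
}

ELECTRON_MASS: float = 0.00054857991
#: Mass of a proton: m(1H) - m(e).
PROTON_MASS: float = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_HILL_SPECIAL = ("C", "H")


@dataclass(frozen=True)
class Formula(Mapping):
    """Immutable element -> count map with monoisotopic-mass semantics.

    Counts are non-negative integers; elements with count zero are dropped,
    so two formulas are equal iff all stored counts are equal.  The empty
    formula has mass zero.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: Dict[str, int] = {}
        for element, n in dict(self.counts).items():
            if element not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {element!r}")
            if not isinstance(n, (int,)) or isinstance(n, bool):
                raise ValueError(f"count for {element} must be an integer, got {n!r}")
            if n < 0:
                raise ValueError(f"negative count for {element}: {n}")
            if n > 0:
                clean[element] = n
        object.__setattr__(self, "counts", clean)

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, element: str) -> int:
        return self.counts[element]

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    def get(self, element: str, default: int = 0) -> int:
        return self.counts.get(element, default)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    # Arithmetic -----------------------------------------------------------
    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return Formula(merged)

    def __sub__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            new = merged.get(el, 0) - n
            if new < 0:
                raise ValueError(
                    f"delta not applicable: removing {n} x {el} leaves a negative count"
                )
            merged[el] = new
        return Formula(merged)

    @property
    def is_empty(self) -> bool:
        return not self.counts

    def hill(self) -> str:
        """Hill-order string: C, H first (when carbon present), then alphabetic."""
        parts = []
        if "C" in self.counts:
            order = [e for e in _HILL_SPECIAL if e in self.counts]
            order += sorted(e for e in self.counts if e not in _HILL_SPECIAL)
        else:
            order = sorted(self.counts)
        for el in order:
            n = self.counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style element-count string such as ``"C25H32O10"``.

    Counts default to 1; any element order is accepted and repeated symbols
    accumulate.  Raises ``ValueError`` on unknown symbols or malformed input
    (e.g. ``"C-3H"``).
    """
    if not isinstance(text, str) or not text.strip():
        raise ValueError(f"empty or non-string formula: {text!r}")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        element, digits = m.group(1), m.group(2)
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return Formula(counts)


def monoisotopic_mass(f: Formula) -> float:
    """Sum of element monoisotopic masses, in Da (0.0 for the empty formula)."""
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in f.items())


@dataclass(frozen=True)
class FormulaDelta:
    """A net formula change: ``added`` is appended, ``removed`` subtracted."""

    added: Formula = field(default_factory=Formula)
    removed: Formula = field(default_factory=Formula)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.added) - monoisotopic_mass(self.removed)


def apply_delta(f: Formula, d: FormulaDelta) -> Formula:
    """Apply a delta; raises ``ValueError`` if any element count would go negative."""
    return (f + d.added) - d.removed


def mz_protonated(f: Formula) -> float:
    """m/z of the singly protonated molecule [M+H]+ of a neutral formula."""
    if f.is_empty:
        raise ValueError("cannot protonate the empty formula")
    return monoisotopic_mass(f) + PROTON_MASS


def cation_mz(f: Formula) -> float:
    """m/z of an even-electron cation whose formula already carries the charge.

    Used for fragment ions printed as e.g. C4H10N+ : the m/z is the neutral
    element-mass sum minus one electron.
    """
    if f.is_empty:
        raise ValueError("cannot compute cation m/z of the empty formula")
    return monoisotopic_mass(f) - ELECTRON_MASS


@dataclass(frozen=True)
class IsotopeTagPair:
    """A light/heavy derivatization reagent pair (e.g. DMED / d4-DMED)."""

    light: Formula
    heavy: Formula
    label_count: int

    @property
    def shift_per_label(self) -> float:
        return MONOISOTOPIC_MASS["D"] - MONOISOTOPIC_MASS["H"]

    @property
    def mass_shift(self) -> float:
        """Total heavy - light channel shift in Da."""
        return self.label_count * self.shift_per_label

    def __post_init__(self) -> None:
        expected = self.label_count * self.shift_per_label
        actual = monoisotopic_mass(self.heavy) - monoisotopic_mass(self.light)
        if abs(actual - expected) > 1e-4:
            raise ValueError(
                f"heavy-light formula mass difference {actual:.5f} does not match "
                f"{self.label_count} labels ({expected:.5f})"
            )


def heavy_mz(light_mz: float, tag: IsotopeTagPair) -> float:
    """Heavy-channel m/z for a given light-channel m/z (constant shift)."""
    if light_mz < 0:
        raise ValueError("light m/z must be non-negative")
    return light_mz + tag.mass_shift


# Fixed chemistry of the workflow -----------------------------------------

#: Glucosylation: net addition of an anhydroglucose unit.
GLUCOSYLATION = FormulaDelta(added=parse_formula("C6H10O5"))

#: DMED amide formation on a free carboxyl: +C4H12N2 -H2O.
DMED_AMIDATION = FormulaDelta(added=parse_formula("C4H12N2"), removed=parse_formula("H2O"))

#: DMED / d4-DMED reagent pair; channel shift 4 x (D - H) = +4.0251 Da.
DMED_TAG = IsotopeTagPair(
    light=parse_formula("C4H12N2"),
    heavy=parse_formula("C4H8D4N2"),
    label_count=4,
)


def export_element_masses(path) -> None:
    """Write the element-mass constants to a CSV for audit."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["symbol", "monoisotopic_mass_da"])
        for el, mass in sorted(MONOISOTOPIC_MASS.items()):
            writer.writerow([el, f"{mass:.8f}"])
        writer.writerow(["e-", f"{ELECTRON_MASS:.8f}"])
        writer.writerow(["proton", f"{PROTON_MASS:.8f}"])
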