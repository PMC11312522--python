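"""Elemental-formula arithmetic for targeted metabolomics.

Monoisotopic neutral masses, adduct m/z, heavy-carbon isotopologue m/z
shifts, and ppm mass-tolerance windows. Atomic monoisotopic masses come
from the NIST table embedded in :mod:`pyteomics.mass`, so no network
access is ever required and results are reproducible to the precision of
that table (>= 6 decimals).

Only singly charged adducts are supported; the adduct registry is
extensible with ``register_ion_type`` for libraries that use other ion
types. Heavy-isotope shifts model carbon only (the tracer of interest is
uniformly 13C-labeled glucose).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

from pyteomics.mass import nist_mass

__all__ = [
    "PROTON_MASS",
    "DELTA_C13",
    "ElementalFormula",
    "IonType",
    "ION_TYPES",
    "get_ion_type",
    "register_ion_type",
    "monoisotopic_mass",
    "theoretical_mz",
    "ppm_window",
]

#: Mass of a proton in Da (CODATA).
PROTON_MASS = 1.00727646688

#: Mass difference between 13C and 12C in Da.
DELTA_C13 = nist_mass["C"][13][0] - nist_mass["C"][12][0]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unparseable or chemically invalid formulas."""


@dataclass(frozen=True)
class ElementalFormula:
    """An elemental composition, e.g. C6H12O6, in Hill notation.

    Parameters
    ----------
    element_counts
        Mapping from element symbol to a positive integer count.
    """

    element_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        counts = dict(self.element_counts)
        if not counts:
            raise FormulaError("empty formula: at least one element required")
        for el, n in counts.items():
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"count for element {el!r} must be a non-negative integer, got {n!r}")
        if all(n == 0 for n in counts.values()):
            raise FormulaError("empty formula: all element counts are zero")
        object.__setattr__(self, "element_counts", counts)

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-notation formula string such as ``"C6H12O6"``."""
        s = text.strip()
        if not s:
            raise FormulaError("empty formula string")
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(s):
            if m.start() != pos:
                raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
            el, digits = m.groups()
            counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
            pos = m.end()
        if pos != len(s):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        return cls(counts)

    @property
    def carbon_count(self) -> int:
        return self.element_counts.get("C", 0)

    def __str__(self) -> str:  # Hill order: C, H, then alphabetical
        counts = dict(self.element_counts)
        parts = []
        for el in ("C", "H"):
            if counts.get(el):
                n = counts.pop(el)
                parts.append(el if n == 1 else f"{el}{n}")
        for el in sorted(counts):
            if counts[el]:
                parts.append(el if counts[el] == 1 else f"{el}{counts[el]}")
        return "".join(parts)


@dataclass(frozen=True)
class IonType:
    """A singly charged adduct: label, charge sign and mass offset in Da."""

    label: str
    charge_sign: int
    mass_delta: float

    def __post_init__(self) -> None:
        if self.charge_sign not in (+1, -1):
            raise ValueError(f"only singly charged adducts supported, got charge {self.charge_sign}")

    @property
    def polarity(self) -> str:
        """Acquisition polarity this ion appears in: ``'+'`` or ``'-'``."""
        return "+" if self.charge_sign > 0 else "-"


ION_TYPES: dict[str, IonType] = {
    "[M+H]+": IonType("[M+H]+", +1, +PROTON_MASS),
    "[M-H]-": IonType("[M-H]-", -1, -PROTON_MASS),
}


def _normalize_ion_label(label: str) -> str:
    # tolerate unicode minus signs from hand-edited library tables
    return label.replace("−", "-").replace("–", "-").strip()


def get_ion_type(label: str) -> IonType:
    """Look up an adduct by label, e.g. ``"[M+H]+"``."""
    key = _normalize_ion_label(label)
    try:
        return ION_TYPES[key]
    except KeyError:
        known = ", ".join(sorted(ION_TYPES))
        raise KeyError(f"unknown ion type {label!r}; known: {known}. Use register_ion_type() to add adducts.") from None


def register_ion_type(label: str, mass_delta: float, charge_sign: int) -> IonType:
    """Register a custom singly charged adduct and return it."""
    ion = IonType(_normalize_ion_label(label), charge_sign, mass_delta)
    ION_TYPES[ion.label] = ion
    return ion


def monoisotopic_mass(formula: ElementalFormula | str) -> float:
    """Monoisotopic neutral mass of a formula in Da.

    Sums count x monoisotopic atomic mass over all elements, using the
    embedded NIST atomic-mass table.

    Raises
    ------
    FormulaError
        If an element symbol is not in the mass table.
    """
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    total = 0.0
    for el, n in formula.element_counts.items():
        try:
            el_mass = nist_mass[el][0][0]
        except KeyError:
            raise FormulaError(f"unknown element symbol {el!r}") from None
        total += n * el_mass
    return total


def theoretical_mz(formula: ElementalFormula | str, ion: IonType | str, iso_k: int = 0) -> float:
    """Theoretical m/z of the m+k isotopologue of ``formula`` as ``ion``.

    m/z = (M + ion.mass_delta + k * (13C - 12C)) / |z|, with |z| = 1.

    ``iso_k`` is the number of heavy-carbon (13C) substitutions; it must
    not exceed the formula's carbon count.
    """
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    if isinstance(ion, str):
        ion = get_ion_type(ion)
    if iso_k < 0:
        raise ValueError(f"isotopologue index must be >= 0, got {iso_k}")
    if iso_k > formula.carbon_count:
        raise ValueError(
            f"isotopologue index {iso_k} exceeds carbon count {formula.carbon_count} of {formula}"
        )
    return monoisotopic_mass(formula) + ion.mass_delta + iso_k * DELTA_C13


def ppm_window(mz: float, tol_ppm: float) -> tuple[float, float]:
    """Symmetric relative mass window ``mz * (1 -/+ tol_ppm * 1e-6)``."""
    if mz <= 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    if tol_ppm <= 0:
        raise ValueError(f"ppm tolerance must be positive, got {tol_ppm}")
    return mz * (1.0 - tol_ppm * 1e-6), mz * (1.0 + tol_ppm * 1e-6)
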