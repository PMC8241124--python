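"""Elemental chemistry and monoisotopic mass arithmetic.

Everything downstream (peptides, glycans, fragment ions) is built from
elemental formulas, so that standard modifications and glycans share a
single mass code path.  Only monoisotopic masses are supported: the
pipeline targets high-resolution Orbitrap-class data where average
masses are never matched.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

# Monoisotopic masses of the light isotope, Da (CODATA/IUPAC values).
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "Se": 79.9165218,
}

PROTON_MASS = 1.007276

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Formula(dict):
    """Elemental formula as an element -> count mapping.

    Behaves like a dict with non-negative integer counts; absent
    elements are count zero.  Supports ``+`` and ``-`` element-wise;
    subtraction below zero raises ``ValueError``.
    """

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargs: int):
        super().__init__()
        merged: dict[str, int] = dict(counts or {})
        merged.update(kwargs)
        for element, count in merged.items():
            if count < 0:
                raise ValueError(f"negative count for element {element!r}")
            if count:
                self[element] = int(count)

    def __add__(self, other: "Formula") -> "Formula":
        out = dict(self)
        for element, count in other.items():
            out[element] = out.get(element, 0) + count
        return Formula(out)

    def __sub__(self, other: "Formula") -> "Formula":
        out = dict(self)
        for element, count in other.items():
            new = out.get(element, 0) - count
            if new < 0:
                raise ValueError(
                    f"subtraction yields negative count for element {element!r}"
                )
            out[element] = new
        return Formula(out)

    def __str__(self) -> str:
        parts = []
        # Hill-ish ordering: C, H, then alphabetical.
        for element in sorted(self, key=lambda e: (e != "C", e != "H", e)):
            count = self[element]
            parts.append(element if count == 1 else f"{element}{count}")
        return "".join(parts)


def parse_formula(text: str) -> Formula:
    """Parse a chemical formula string such as ``"C6H10O5"``.

    Underscore-separated subscripts (``"C_6_H_10_O_5_"``) are accepted,
    matching the way compositions are often printed in tables.  An
    element without a trailing number has count 1; the empty string is
    the empty formula.
    """
    cleaned = text.replace("_", "").strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(cleaned):
        m = _FORMULA_TOKEN.match(cleaned, pos)
        if not m or not m.group(1):
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        element, digits = m.group(1), m.group(2)
        if element not in ELEMENT_MASSES:
            raise ValueError(f"unknown element symbol {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return Formula(counts)


def formula_mass(f: Mapping[str, int]) -> float:
    """Monoisotopic mass of a formula in Da."""
    total = 0.0
    for element, count in f.items():
        try:
            total += count * ELEMENT_MASSES[element]
        except KeyError:
            raise ValueError(f"element {element!r} missing from mass table") from None
    return total


WATER = parse_formula("H2O")
WATER_MASS = formula_mass(WATER)

# Residue (dehydrated amino acid) formulas for the 20 canonical residues.
AMINO_ACID_FORMULAS: dict[str, Formula] = {
    "G": parse_formula("C2H3NO"),
    "A": parse_formula("C3H5NO"),
    "S": parse_formula("C3H5NO2"),
    "P": parse_formula("C5H7NO"),
    "V": parse_formula("C5H9NO"),
    "T": parse_formula("C4H7NO2"),
    "C": parse_formula("C3H5NOS"),
    "L": parse_formula("C6H11NO"),
    "I": parse_formula("C6H11NO"),
    "N": parse_formula("C4H6N2O2"),
    "D": parse_formula("C4H5NO3"),
    "Q": parse_formula("C5H8N2O2"),
    "K": parse_formula("C6H12N2O"),
    "E": parse_formula("C5H7NO3"),
    "M": parse_formula("C5H9NOS"),
    "H": parse_formula("C6H7N3O"),
    "F": parse_formula("C9H9NO"),
    "R": parse_formula("C6H12N4O"),
    "Y": parse_formula("C9H9NO2"),
    "W": parse_formula("C11H10N2O"),
}

AMINO_ACID_MASSES: dict[str, float] = {
    aa: formula_mass(f) for aa, f in AMINO_ACID_FORMULAS.items()
}


@dataclass(frozen=True)
class ModificationDef:
    """A covalent modification defined by its elemental delta.

    ``target`` is a residue letter, or ``"N-term"``/``"C-term"`` for
    terminal modifications.
    """

    name: str
    target: str
    formula_delta: Formula = field(compare=False)
    fixed: bool = False

    @property
    def mass(self) -> float:
        return formula_mass(self.formula_delta)


# Standard shipped modifications: carbamidomethylated cysteine is fixed
# (iodoacetamide alkylation), oxidised methionine and N-terminal
# acetylation are variable.
CARBAMIDOMETHYL = ModificationDef("Carbamidomethyl", "C", parse_formula("C2H3NO"), fixed=True)
OXIDATION_M = ModificationDef("Oxidation", "M", parse_formula("O"), fixed=False)
ACETYL_NTERM = ModificationDef("Acetyl", "N-term", parse_formula("C2H2O"), fixed=False)

DEFAULT_MODIFICATIONS: tuple[ModificationDef, ...] = (
    CARBAMIDOMETHYL,
    OXIDATION_M,
    ACETYL_NTERM,
)


def load_modifications(path: str | Path) -> list[ModificationDef]:
    """Load modification definitions from a TSV file.

    Columns: name, target, formula, fixed (true/false).  Lines starting
    with ``#`` are comments.
    """
    mods = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"expected 4 tab-separated fields, got {line!r}")
        name, target, formula, fixed = fields
        mods.append(
            ModificationDef(name, target, parse_formula(formula), fixed.lower() == "true")
        )
    return mods


def peptide_mass(
    sequence: str,
    mods: Iterable[tuple[int, ModificationDef]] = (),
) -> float:
    """Neutral monoisotopic mass of a (modified) peptide in Da.

    ``mods`` are ``(position, definition)`` pairs; positions are 1-based
    within the peptide, with 0 denoting the N-terminus.  At most one
    modification per position.  The empty peptide has the mass of water.
    """
    total = WATER_MASS
    for aa in sequence:
        try:
            total += AMINO_ACID_MASSES[aa]
        except KeyError:
            raise ValueError(f"unknown amino acid residue {aa!r}") from None
    seen: set[int] = set()
    for position, mod in mods:
        if position in seen:
            raise ValueError(f"two modifications on position {position}")
        seen.add(position)
        total += mod.mass
    return total


def mz_from_mass(neutral_mass: float, charge: int) -> float:
    """m/z of a positive ion with the given neutral mass and charge."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def neutral_mass_from_mz(mz: float, charge: int) -> float:
    """Inverse of :func:`mz_from_mass`."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz * charge - charge * PROTON_MASS
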