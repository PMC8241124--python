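"""Glycan compositions of the two *Haloferax volcanii* N-glycosylation
pathways, plus the O-linked disaccharide, and their Y/B fragment ladders.

The AglB pathway builds a pentasaccharide (Hex, then hexuronic acids and a
methylated hexuronic acid, capped by a second hexose); the Agl15 pathway
builds a sulfated tetrasaccharide starting with a sulfated hexose.  Each
biosynthetic intermediate is a legitimate search composition in its own
right, so the default table carries every prefix that is observed in vivo.

Glycans are modeled as linear chains, written peptide-proximal residue
first.  Residue formulas are the dehydrated monosaccharides, so a glycan's
mass is simply the sum of its residue masses (glycosidic attachment is a
condensation; no extra water term).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .chem import Formula, formula_mass, mz_from_mass, parse_formula


class Pathway(str, Enum):
    AglB = "AglB"
    Agl15 = "Agl15"
    O_linked = "O_linked"


@dataclass(frozen=True)
class MonosaccharideResidue:
    """A dehydrated monosaccharide residue."""

    symbol: str
    residue_formula: Formula = field(compare=False)

    @property
    def mass(self) -> float:
        return formula_mass(self.residue_formula)


# Dehydrated residue formulas derived from monosaccharide chemistry.
MONOSACCHARIDES: dict[str, MonosaccharideResidue] = {
    "Hex": MonosaccharideResidue("Hex", parse_formula("C6H10O5")),
    "HexA": MonosaccharideResidue("HexA", parse_formula("C6H8O6")),
    "MeHexA": MonosaccharideResidue("MeHexA", parse_formula("C7H10O6")),
    "dHex": MonosaccharideResidue("dHex", parse_formula("C6H10O4")),
    "SO3Hex": MonosaccharideResidue("SO3Hex", parse_formula("C6H10O8S")),
}


@dataclass(frozen=True)
class GlycanComposition:
    """A linear glycan, residues listed peptide-proximal first."""

    name: str
    residues: tuple[str, ...]
    pathway: Pathway
    target_residues: frozenset[str]

    def __post_init__(self):
        if not self.residues:
            raise ValueError("glycan must have at least one residue")
        for symbol in self.residues:
            if symbol not in MONOSACCHARIDES:
                raise ValueError(f"unknown monosaccharide symbol {symbol!r}")
        if self.pathway in (Pathway.AglB, Pathway.Agl15):
            if self.target_residues != frozenset("N"):
                raise ValueError(f"{self.pathway.value} glycans target N only")
        elif self.target_residues != frozenset("ST"):
            raise ValueError("O-linked glycans target S/T")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def formula(self) -> Formula:
        total = Formula()
        for symbol in self.residues:
            total = total + MONOSACCHARIDES[symbol].residue_formula
        return total

    def __str__(self) -> str:
        return self.name


MONOSACCHARIDE_MASSES: dict[str, float] = {
    symbol: residue.mass for symbol, residue in MONOSACCHARIDES.items()
}

_GLYCAN_MASS_CACHE: dict[tuple[str, ...], float] = {}


def glycan_mass(g: GlycanComposition) -> float:
    """Neutral mass added to a peptide by the glycan, in Da."""
    mass = _GLYCAN_MASS_CACHE.get(g.residues)
    if mass is None:
        mass = sum(MONOSACCHARIDE_MASSES[symbol] for symbol in g.residues)
        _GLYCAN_MASS_CACHE[g.residues] = mass
    return mass


def _n_glycan(name: str, *residues: str, pathway: Pathway) -> GlycanComposition:
    return GlycanComposition(name, tuple(residues), pathway, frozenset("N"))


def default_glycan_table() -> list[GlycanComposition]:
    """The default search space: 5 AglB-type and 4 Agl15-type N-glycans
    (the mature glycans and their biosynthetic intermediates) plus the
    O-linked Hex(2) disaccharide on S/T."""
    return [
        _n_glycan("Hex(1)", "Hex", pathway=Pathway.AglB),
        _n_glycan("Hex(1)HexA(1)", "Hex", "HexA", pathway=Pathway.AglB),
        _n_glycan("Hex(1)HexA(2)", "Hex", "HexA", "HexA", pathway=Pathway.AglB),
        _n_glycan(
            "Hex(1)HexA(2)MeHexA(1)",
            "Hex", "HexA", "HexA", "MeHexA",
            pathway=Pathway.AglB,
        ),
        _n_glycan(
            "Hex(2)HexA(2)MeHexA(1)",
            "Hex", "HexA", "HexA", "MeHexA", "Hex",
            pathway=Pathway.AglB,
        ),
        _n_glycan("SO3Hex(1)", "SO3Hex", pathway=Pathway.Agl15),
        _n_glycan("SO3Hex(1)Hex(1)", "SO3Hex", "Hex", pathway=Pathway.Agl15),
        _n_glycan("SO3Hex(1)Hex(2)", "SO3Hex", "Hex", "Hex", pathway=Pathway.Agl15),
        _n_glycan(
            "SO3Hex(1)Hex(2)dHex(1)",
            "SO3Hex", "Hex", "Hex", "dHex",
            pathway=Pathway.Agl15,
        ),
        GlycanComposition("Hex(2)", ("Hex", "Hex"), Pathway.O_linked, frozenset("ST")),
    ]


# Full chemical compositions as printed in the published search-space
# table.  The Hex(1)HexA(1) row prints the HexA residue formula alone
# (C6H8O6) rather than the two-residue sum (C12H18O11); the residue-sum
# rule is used throughout and the discrepancy is surfaced as a warning.
PRINTED_COMPOSITIONS: dict[str, str] = {
    "Hex(1)": "C6H10O5",
    "Hex(1)HexA(1)": "C6H8O6",
    "Hex(1)HexA(2)": "C18H26O17",
    "Hex(1)HexA(2)MeHexA(1)": "C25H36O23",
    "Hex(2)HexA(2)MeHexA(1)": "C31H46O28",
    "SO3Hex(1)": "C6H10O8S1",
    "SO3Hex(1)Hex(1)": "C12H20O13S1",
    "SO3Hex(1)Hex(2)": "C18H30O18S1",
    "SO3Hex(1)Hex(2)dHex(1)": "C24H40O22S1",
    "Hex(2)": "C12H20O10",
}


def validate_printed_compositions(
    glycans: list[GlycanComposition] | None = None,
    tol_da: float = 2e-3,
) -> dict[str, float]:
    """Compare residue-sum masses against the printed full compositions.

    Returns ``{glycan name: |residue-sum mass - printed mass|}`` and
    warns for any row where the two disagree beyond ``tol_da``.
    """
    glycans = glycans if glycans is not None else default_glycan_table()
    deviations: dict[str, float] = {}
    for g in glycans:
        printed = PRINTED_COMPOSITIONS.get(g.name)
        if printed is None:
            continue
        dev = abs(glycan_mass(g) - formula_mass(parse_formula(printed)))
        deviations[g.name] = dev
        if dev > tol_da:
            warnings.warn(
                f"printed composition {printed} for {g.name} disagrees with the "
                f"residue sum {g.formula} by {dev:.4f} Da; using the residue sum",
                stacklevel=2,
            )
    return deviations


@dataclass(frozen=True)
class GlycanIonLadder:
    """Neutral Y/B fragment masses of a glycopeptide.

    ``y_masses[k]`` is the peptide plus the k proximal residues (Y0 is
    the bare peptide); ``b_masses[k-1]`` is the oxonium-equivalent
    neutral mass of the k terminal residues (B1 is the liberated
    terminal sugar).
    """

    y_masses: tuple[float, ...]
    b_masses: tuple[float, ...]

    def y_mz(self, k: int, charge: int = 1) -> float:
        return mz_from_mass(self.y_masses[k], charge)

    def b_mz(self, k: int, charge: int = 1) -> float:
        return mz_from_mass(self.b_masses[k - 1], charge)


def ion_ladder(peptide_mass: float, g: GlycanComposition) -> GlycanIonLadder:
    """Y/B ladder from successive cleavage of the interglycosidic bonds."""
    if peptide_mass <= 0:
        raise ValueError("peptide mass must be positive")
    residue_masses = [MONOSACCHARIDE_MASSES[s] for s in g.residues]
    y = [peptide_mass]
    for m in residue_masses:
        y.append(y[-1] + m)
    b = []
    total = 0.0
    for m in reversed(residue_masses):
        total += m
        b.append(total)
    return GlycanIonLadder(tuple(y), tuple(b))


def write_glycan_table(glycans: list[GlycanComposition], path: str | Path) -> None:
    """Write a glycan table as TSV (name, target, pathway, residue_list)."""
    lines = ["name\ttarget\tpathway\tresidue_list"]
    for g in glycans:
        target = "N" if g.target_residues == frozenset("N") else "S/T"
        lines.append(f"{g.name}\t{target}\t{g.pathway.value}\t{'-'.join(g.residues)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_glycan_table(path: str | Path) -> list[GlycanComposition]:
    """Read a glycan table written by :func:`write_glycan_table`."""
    glycans = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        name, target, pathway, residue_list = line.split("\t")
        targets = frozenset("N") if target == "N" else frozenset("ST")
        glycans.append(
            GlycanComposition(name, tuple(residue_list.split("-")), Pathway(pathway), targets)
        )
    return glycans
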