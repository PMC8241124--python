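"""In-silico proteolysis, peptidoform enumeration and decoy generation.

Digestion is fully specific (both termini at cleavage sites or protein
termini).  Peptidoforms carry fixed modifications on every eligible
residue, up to a configurable number of variable modifications, and —
for glycopeptide searches — one glycan composition placed on up to two
eligible sites, since search engines handle one glycan type per search.
"""

from __future__ import annotations

import zlib
import random
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

from pyteomics import fasta as _fasta

from .chem import (
    DEFAULT_MODIFICATIONS,
    ModificationDef,
    peptide_mass,
)
from .glycans import GlycanComposition, glycan_mass


@dataclass(frozen=True)
class ProteaseRule:
    """C-terminal cleavage rule: cut after ``cleave_after`` unless the
    next residue is in ``blocked_by_next``."""

    name: str
    cleave_after: frozenset[str]
    blocked_by_next: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.cleave_after:
            raise ValueError("cleave_after must be non-empty")


TRYPSIN = ProteaseRule("trypsin", frozenset("KR"), frozenset("P"))
GLUC = ProteaseRule("gluc", frozenset("E"))
GLUC_DE = ProteaseRule("gluc_de", frozenset("DE"))

PROTEASES = {p.name: p for p in (TRYPSIN, GLUC, GLUC_DE)}


@dataclass(frozen=True)
class PeptideSpan:
    """A peptide located on its parent protein (1-based inclusive)."""

    protein_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int = 0

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError("invalid span coordinates")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("sequence length does not match coordinates")


def cleavage_sites(sequence: str, rule: ProteaseRule) -> list[int]:
    """0-based indices i such that the bond after ``sequence[i]`` is cut."""
    sites = []
    for i, aa in enumerate(sequence[:-1]):
        if aa in rule.cleave_after and sequence[i + 1] not in rule.blocked_by_next:
            sites.append(i)
    return sites


def digest(
    protein_id: str,
    sequence: str,
    rule: ProteaseRule,
    max_missed: int = 0,
) -> list[PeptideSpan]:
    """All fully-specific peptides with 0..max_missed missed cleavages."""
    if not sequence:
        raise ValueError("empty protein sequence")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    # Boundaries: start indices of the 0-missed-cleavage fragments.
    cuts = [i + 1 for i in cleavage_sites(sequence, rule)]
    bounds = [0] + cuts + [len(sequence)]
    spans = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for j in range(i, min(i + max_missed + 1, n_frag)):
            start, end = bounds[i], bounds[j + 1]
            spans.append(
                PeptideSpan(
                    protein_id,
                    start + 1,
                    end,
                    sequence[start:end],
                    missed_cleavages=j - i,
                )
            )
    return spans


@dataclass(frozen=True)
class Peptidoform:
    """A peptide plus its exact modification state.

    Positions are 1-based within the peptide; position 0 denotes the
    N-terminus.  At most one modification of any kind per position;
    every glycan sits on a residue in its ``target_residues``.
    """

    span: PeptideSpan
    fixed_mods: tuple[tuple[int, ModificationDef], ...] = ()
    variable_mods: tuple[tuple[int, ModificationDef], ...] = ()
    glyco_mods: tuple[tuple[int, GlycanComposition], ...] = ()
    is_decoy: bool = False
    neutral_mass: float = field(default=0.0, compare=False)

    def __post_init__(self):
        seq = self.span.sequence
        positions = [p for p, _ in self.fixed_mods + self.variable_mods] + [
            p for p, _ in self.glyco_mods
        ]
        if len(positions) != len(set(positions)):
            raise ValueError("two modifications on one position")
        for pos, g in self.glyco_mods:
            if seq[pos - 1] not in g.target_residues:
                raise ValueError(
                    f"glycan {g.name} on ineligible residue {seq[pos - 1]!r}"
                )
        if self.neutral_mass == 0.0:
            object.__setattr__(self, "neutral_mass", self._compute_mass())

    def _compute_mass(self) -> float:
        mass = peptide_mass(self.span.sequence, self.fixed_mods + self.variable_mods)
        for _, g in self.glyco_mods:
            mass += glycan_mass(g)
        return mass

    @property
    def sequence(self) -> str:
        return self.span.sequence

    @property
    def is_glyco(self) -> bool:
        return bool(self.glyco_mods)

    def n_canonical_sequon_sites(self) -> int:
        """Glycosylated N residues sitting in a peptide-local N-X-S/T
        sequon.  Used as a placement prior when fragment evidence cannot
        distinguish isobaric glycan positions."""
        seq = self.sequence
        count = 0
        for pos, g in self.glyco_mods:
            if (
                "N" in g.target_residues
                and seq[pos - 1] == "N"
                and pos + 2 <= len(seq)
                and seq[pos + 1] in "ST"
            ):
                count += 1
        return count

    def key(self) -> str:
        """Canonical peptidoform string: sequence plus sorted mods."""
        mods = [(pos, m.name) for pos, m in self.fixed_mods + self.variable_mods]
        mods += [(pos, g.name) for pos, g in self.glyco_mods]
        tag = ";".join(f"{name}@{pos}" for pos, name in sorted(mods))
        body = f"{self.sequence}[{tag}]" if tag else self.sequence
        return ("decoy_" if self.is_decoy else "") + body


def eligible_positions(sequence: str, target: str) -> list[int]:
    """1-based positions of ``target`` residues (0 for the N-terminus)."""
    if target == "N-term":
        return [0]
    if target == "C-term":
        return [len(sequence)]
    return [i + 1 for i, aa in enumerate(sequence) if aa == target]


def enumerate_peptidoforms(
    span: PeptideSpan,
    glycan: GlycanComposition | None = None,
    max_variable: int = 1,
    max_glyco_sites: int = 2,
    modifications: Sequence[ModificationDef] = DEFAULT_MODIFICATIONS,
    glyco_only: bool = False,
    is_decoy: bool = False,
) -> list[Peptidoform]:
    """All modification states of a peptide span for one search.

    Fixed modifications go on every eligible position.  Variable
    modifications are combined up to ``max_variable`` at a time.  When a
    glycan is given, all placements on 1..``max_glyco_sites`` eligible
    residues are produced (plus the unglycosylated form unless
    ``glyco_only``); positions already carrying another modification are
    not glycosylated.
    """
    seq = span.sequence
    fixed = tuple(
        (pos, mod)
        for mod in modifications
        if mod.fixed
        for pos in eligible_positions(seq, mod.target)
    )
    fixed_positions = {pos for pos, _ in fixed}

    variable_sites = [
        (pos, mod)
        for mod in modifications
        if not mod.fixed
        for pos in eligible_positions(seq, mod.target)
        if pos not in fixed_positions
    ]
    var_choices: list[tuple[tuple[int, ModificationDef], ...]] = [()]
    for k in range(1, max_variable + 1):
        for combo in combinations(variable_sites, k):
            if len({pos for pos, _ in combo}) == k:
                var_choices.append(combo)

    base_mass = peptide_mass(seq, fixed)
    g_mass = glycan_mass(glycan) if glycan is not None else 0.0
    forms = []
    for var in var_choices:
        var_mass = base_mass + sum(m.mass for _, m in var)
        taken = fixed_positions | {pos for pos, _ in var}
        glyco_choices: list[tuple[tuple[int, GlycanComposition], ...]] = (
            [] if glyco_only else [()]
        )
        if glycan is not None:
            sites = [
                pos
                for target in glycan.target_residues
                for pos in eligible_positions(seq, target)
                if pos not in taken
            ]
            sites.sort()
            for k in range(1, max_glyco_sites + 1):
                for combo in combinations(sites, k):
                    glyco_choices.append(tuple((pos, glycan) for pos in combo))
        for glyco in glyco_choices:
            forms.append(
                Peptidoform(
                    span,
                    fixed_mods=fixed,
                    variable_mods=var,
                    glyco_mods=glyco,
                    is_decoy=is_decoy,
                    neutral_mass=var_mass + g_mass * len(glyco),
                )
            )
    return forms


def _decoy_permutation(sequence: str, seed: int) -> list[int]:
    """Deterministic shuffle of positions 0..n-2 (C-terminus pinned)."""
    n = len(sequence)
    order = list(range(n - 1))
    rng = random.Random(seed ^ zlib.crc32(sequence.encode()))
    rng.shuffle(order)
    return order + [n - 1]


def make_decoy(p: Peptidoform, seed: int = 0) -> Peptidoform:
    """Shuffled-sequence decoy of a peptidoform.

    The C-terminal residue is held fixed to preserve protease
    specificity; every site modification travels with its residue, so
    eligibility and mass are preserved.  Deterministic for a given
    (peptidoform, seed).
    """
    seq = p.sequence
    if len(seq) < 2:
        raise ValueError("peptide too short to shuffle")
    order = _decoy_permutation(seq, seed)
    new_seq = "".join(seq[i] for i in order)
    # old 1-based position -> new 1-based position
    remap = {old + 1: new + 1 for new, old in enumerate(order)}
    remap[0] = 0  # N-terminus stays terminal

    span = PeptideSpan(
        p.span.protein_id, p.span.start, p.span.end, new_seq, p.span.missed_cleavages
    )
    return Peptidoform(
        span,
        fixed_mods=tuple(sorted(((remap[pos], m) for pos, m in p.fixed_mods),
                                key=lambda x: x[0])),
        variable_mods=tuple(sorted(((remap[pos], m) for pos, m in p.variable_mods),
                                   key=lambda x: x[0])),
        glyco_mods=tuple(sorted(((remap[pos], g) for pos, g in p.glyco_mods),
                                key=lambda x: x[0])),
        is_decoy=True,
        neutral_mass=p.neutral_mass,  # shuffling preserves composition
    )


def decoy_span(span: PeptideSpan, seed: int = 0) -> PeptideSpan:
    """Shuffled-sequence decoy of a peptide span (decoy-database style).

    The C-terminal residue is held fixed to preserve protease
    specificity; modification eligibility is then recomputed on the
    shuffled sequence by enumerating peptidoforms on the result.
    Deterministic for a given (span sequence, seed).
    """
    seq = span.sequence
    if len(seq) < 2:
        raise ValueError("peptide too short to shuffle")
    order = _decoy_permutation(seq, seed)
    return PeptideSpan(
        span.protein_id,
        span.start,
        span.end,
        "".join(seq[i] for i in order),
        span.missed_cleavages,
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA; the ID is the first whitespace-delimited
    header token."""
    proteins: dict[str, str] = {}
    with _fasta.read(str(path)) as reader:
        for header, sequence in reader:
            proteins[header.split()[0]] = sequence
    return proteins


def write_fasta(proteins: dict[str, str], path: str | Path) -> None:
    entries = [(pid, seq) for pid, seq in proteins.items()]
    _fasta.write(entries, str(path), file_mode="w")
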