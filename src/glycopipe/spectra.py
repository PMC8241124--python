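"""Spectrum model, MGF I/O, fragment-ion generation and matching, the
built-in naive search engine, and the glyco fragment-ion evidence rule.

Backbone b/y ions follow the usual peptide-bond fragmentation
convention.  For glycopeptides, N/O-glycans are labile under HCD, so
each glycan-carrying backbone ion is also emitted in a glycan-less
variant; glyco Y ions (peptide + proximal sugars, Y0 = bare peptide) and
B/oxonium ions (terminal sugars) come from interglycosidic cleavage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf as _mgf

from .chem import (
    AMINO_ACID_MASSES,
    WATER_MASS,
    mz_from_mass,
    neutral_mass_from_mz,
)
from .digestion import Peptidoform
from .glycans import glycan_mass, ion_ladder

SEARCHABLE_CHARGES = frozenset(range(2, 7))  # charge 1 and >6 excluded
DEFAULT_MIN_MZ = 130.0  # fixed first mass of the MS2 acquisition window


@dataclass
class Spectrum:
    """A centroided MS2 peak list with its precursor."""

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    mz: np.ndarray
    intensity: np.ndarray
    replicate_id: str = ""
    fraction_id: str = ""
    strain_id: str = ""

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(self.mz <= 0) or np.any(self.intensity < 0):
            raise ValueError("peaks must have positive m/z and non-negative intensity")

    @property
    def searchable(self) -> bool:
        return self.precursor_charge in SEARCHABLE_CHARGES

    @property
    def precursor_neutral_mass(self) -> float:
        return neutral_mass_from_mz(self.precursor_mz, self.precursor_charge)

    def title(self) -> str:
        tokens = [f"id={self.spectrum_id}"]
        if self.strain_id:
            tokens.append(f"strain={self.strain_id}")
        if self.replicate_id:
            tokens.append(f"replicate={self.replicate_id}")
        if self.fraction_id:
            tokens.append(f"fraction={self.fraction_id}")
        return " ".join(tokens)


def _parse_title(title: str) -> dict[str, str]:
    out = {}
    for token in title.split():
        if "=" in token:
            key, value = token.split("=", 1)
            out[key] = value
    return out


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF peak-list file.

    Replicate/fraction/strain labels are parsed from ``key=value``
    tokens in the TITLE line when present.  Charge defaults to 2 when
    absent (searchable spectra always carry one).
    """
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for index, entry in enumerate(reader):
            params = entry["params"]
            try:
                title = params.get("title", "")
                meta = _parse_title(title)
                charge_param = params.get("charge")
                charge = int(charge_param[0]) if charge_param else 2
                spectra.append(
                    Spectrum(
                        spectrum_id=meta.get("id", title or f"index={index}"),
                        precursor_mz=float(params["pepmass"][0]),
                        precursor_charge=charge,
                        mz=entry["m/z array"],
                        intensity=entry["intensity array"],
                        replicate_id=meta.get("replicate", ""),
                        fraction_id=meta.get("fraction", ""),
                        strain_id=meta.get("strain", ""),
                    )
                )
            except (KeyError, ValueError, IndexError) as exc:
                raise ValueError(f"malformed MGF block {index} in {path}: {exc}") from exc
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF, m/z to 5 decimals, metadata in the TITLE."""
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": np.round(s.mz, 5),
                "intensity array": np.round(s.intensity, 2),
                "params": {
                    "title": s.title(),
                    "pepmass": round(s.precursor_mz, 5),
                    "charge": f"{s.precursor_charge}+",
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def theoretical_backbone_ions(
    p: Peptidoform,
    max_frag_charge: int = 1,
) -> list[tuple[str, float]]:
    """Theoretical b1..b(n-1) / y1..y(n-1) ions of a peptidoform.

    Site modifications (including glycans) ride on fragments containing
    the modified residue; for glycopeptides a glycan-less variant of
    each glycan-carrying backbone ion is emitted as well (labile-glycan
    convention).  Returns ``(label, mz)`` pairs; labels look like
    ``b3+1`` or ``y5-glycan+2``.
    """
    seq = p.sequence
    n = len(seq)
    if n < 2:
        raise ValueError("peptide must have length >= 2")
    mod_mass = [0.0] * (n + 1)  # index 0 = N-terminus
    glycan_site_mass = [0.0] * (n + 1)
    for pos, mod in p.fixed_mods + p.variable_mods:
        mod_mass[pos] += mod.mass
    for pos, g in p.glyco_mods:
        gm = glycan_mass(g)
        mod_mass[pos] += gm
        glycan_site_mass[pos] += gm

    prefix = [0.0] * (n + 1)  # neutral mass of b_k fragment (sum of residues+mods)
    prefix_glycan = [0.0] * (n + 1)  # glycan mass carried by the prefix
    acc = mod_mass[0]
    acc_g = 0.0
    for k in range(1, n + 1):
        acc += AMINO_ACID_MASSES[seq[k - 1]] + mod_mass[k]
        acc_g += glycan_site_mass[k]
        prefix[k] = acc
        prefix_glycan[k] = acc_g
    total_glycan = acc_g

    ions = []
    for k in range(1, n):
        b_neutral = prefix[k]
        y_neutral = prefix[n] - prefix[k] + WATER_MASS
        for z in range(1, max_frag_charge + 1):
            ions.append((f"b{k}+{z}", mz_from_mass(b_neutral, z)))
            ions.append((f"y{n - k}+{z}", mz_from_mass(y_neutral, z)))
            if prefix_glycan[k] > 0:
                ions.append(
                    (f"b{k}-glycan+{z}", mz_from_mass(b_neutral - prefix_glycan[k], z))
                )
            if total_glycan - prefix_glycan[k] > 0:
                ions.append(
                    (
                        f"y{n - k}-glycan+{z}",
                        mz_from_mass(y_neutral - (total_glycan - prefix_glycan[k]), z),
                    )
                )
    return ions


def theoretical_glyco_ions(
    p: Peptidoform,
    charges: Sequence[int] = (1, 2),
    min_mz: float = 0.0,
) -> list[tuple[str, float]]:
    """Glyco Y/B ions of a glycopeptidoform as ``(label, mz)`` pairs.

    The Y ladder strips the glycan residue by residue from the intact
    peptidoform (for multiply glycosylated peptides the ladder is built
    per site, holding the other sites intact).  B/oxonium ions below
    ``min_mz`` (the acquisition lower bound) are suppressed.
    """
    if not p.is_glyco:
        return []
    ions: list[tuple[str, float]] = []
    seen: set[tuple[str, int]] = set()
    for site, g in p.glyco_mods:
        base = p.neutral_mass - glycan_mass(g)
        ladder = ion_ladder(base, g)
        for k, y_neutral in enumerate(ladder.y_masses):
            for z in charges:
                label = f"Y{k}@{site}+{z}"
                ions.append((label, mz_from_mass(y_neutral, z)))
        for k, b_neutral in enumerate(ladder.b_masses, start=1):
            mz1 = mz_from_mass(b_neutral, 1)
            if mz1 >= min_mz and (g.name, k) not in seen:
                seen.add((g.name, k))
                ions.append((f"B{k}+1", mz1))
    return ions


@dataclass
class FragmentMatchResult:
    """Peak-matching outcome for one spectrum/peptidoform pair."""

    matched_b_backbone: int = 0
    matched_y_backbone: int = 0
    matched_glyco_B: int = 0
    matched_glyco_Y: int = 0
    matched_peak_indices: list[int] = field(default_factory=list)
    matched_labels: list[str] = field(default_factory=list)
    ppm_errors: list[float] = field(default_factory=list)

    @property
    def n_backbone(self) -> int:
        return self.matched_b_backbone + self.matched_y_backbone

    @property
    def distinct_glyco_Y(self) -> int:
        """Distinct Y-ladder rungs matched (charge states collapsed)."""
        rungs = {lab.split("+")[0] for lab in self.matched_labels if lab.startswith("Y")}
        return len(rungs)

    @property
    def distinct_glyco_B(self) -> int:
        rungs = {lab.split("+")[0] for lab in self.matched_labels if lab.startswith("B")}
        return len(rungs)


def match_peaks(
    s: Spectrum,
    theo: Sequence[tuple[str, float]],
    tol_ppm: float,
) -> FragmentMatchResult:
    """Match theoretical ions to the nearest peak within ±tol_ppm
    (inclusive); ties broken toward the higher-intensity peak.  One peak
    may satisfy several theoretical ions."""
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    result = FragmentMatchResult()
    if not theo or s.mz.size == 0:
        return result
    labels = [t[0] for t in theo]
    theo_mz = np.array([t[1] for t in theo])
    n_peaks = s.mz.size
    idx = np.searchsorted(s.mz, theo_mz)
    left = np.clip(idx - 1, 0, n_peaks - 1)
    right = np.clip(idx, 0, n_peaks - 1)
    err_left = (s.mz[left] - theo_mz) / theo_mz * 1e6
    err_right = (s.mz[right] - theo_mz) / theo_mz * 1e6
    ok_left = np.abs(err_left) <= tol_ppm
    ok_right = (np.abs(err_right) <= tol_ppm) & (idx < n_peaks)
    # nearest peak wins; exact-distance ties go to the higher intensity
    d_left = np.where(ok_left, np.abs(err_left), np.inf)
    d_right = np.where(ok_right, np.abs(err_right), np.inf)
    with np.errstate(invalid="ignore"):
        tie = np.abs(d_left - d_right) <= 1e-12
        prefer_right = (d_right < d_left - 1e-12) | (
            tie & (s.intensity[right] > s.intensity[left])
        )
    best = np.where(prefer_right, right, left)
    best_err = np.where(prefer_right, err_right, err_left)
    matched = ok_left | ok_right
    for j in np.flatnonzero(matched):
        label = labels[j]
        result.matched_peak_indices.append(int(best[j]))
        result.matched_labels.append(label)
        result.ppm_errors.append(float(best_err[j]))
        if label.startswith("b"):
            result.matched_b_backbone += 1
        elif label.startswith("y"):
            result.matched_y_backbone += 1
        elif label.startswith("B"):
            result.matched_glyco_B += 1
        elif label.startswith("Y"):
            result.matched_glyco_Y += 1
    return result


def naive_engine_score(
    s: Spectrum,
    p: Peptidoform,
    tol_ppm: float = 10.0,
    max_frag_charge: int = 1,
) -> float:
    """Deterministic built-in engine score; higher is better.

    score = (matched backbone ion count) x ln(1 + matched intensity /
    total intensity).  The ion count is the number of distinct matched
    peaks: a peak satisfying several ion labels (e.g. a backbone ion
    and the glycan-less variant of another) is counted once, so
    isobaric modification placements cannot inflate their score by
    label multiplicity.  Zero when nothing matches.
    """
    theo = theoretical_backbone_ions(p, max_frag_charge=max_frag_charge)
    res = match_peaks(s, theo, tol_ppm)
    if not res.matched_peak_indices:
        return 0.0
    total = float(s.intensity.sum())
    if total <= 0:
        return 0.0
    peak_idx = sorted(set(res.matched_peak_indices))
    matched = float(s.intensity[peak_idx].sum())
    return len(peak_idx) * math.log1p(matched / total)


@dataclass
class PSM:
    """A peptide-spectrum match with its per-engine and combined scores."""

    spectrum_id: str
    peptidoform: Peptidoform
    engine_scores: dict[str, float] = field(default_factory=dict)
    engine_peps: dict[str, float] = field(default_factory=dict)
    combined_pep: float = 1.0
    glyco_evidence: FragmentMatchResult | None = None
    replicate_id: str = ""
    fraction_id: str = ""
    strain_id: str = ""
    # the engine could not distinguish this match from an isobaric
    # alternative within its own search
    ambiguous: bool = False

    @property
    def is_decoy(self) -> bool:
        return self.peptidoform.is_decoy

    @property
    def key(self) -> str:
        return self.peptidoform.key()


def glyco_ion_evidence(
    psms_for_glycopeptide: Sequence[PSM],
    require_oxonium: bool = True,
    min_B: int = 1,
    min_Y: int = 2,
) -> bool:
    """Glycopeptide fragment-ion evidence rule.

    True iff at least one single spectrum of the glycopeptide matches
    >= ``min_Y`` glyco Y ions AND (>= ``min_B`` glyco B/oxonium ions, or
    ``require_oxonium`` is false).  The B requirement is waived for data
    acquired without the low-m/z range where oxonium ions fall.
    """
    if not psms_for_glycopeptide:
        raise ValueError("empty PSM list")
    for psm in psms_for_glycopeptide:
        ev: FragmentMatchResult | None = getattr(psm, "glyco_evidence", None)
        if ev is None:
            continue
        if ev.distinct_glyco_Y >= min_Y and (
            not require_oxonium or ev.distinct_glyco_B >= min_B
        ):
            return True
    return False
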