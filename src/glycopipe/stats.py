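"""Error estimation and the identification filter cascade.

Posterior error probabilities (PEPs) are estimated from the local decoy
density in a ranked concatenated target-decoy list: under the standard
symmetry assumption an incorrect target match is as likely as a decoy
match, so the local error rate is twice the decoy fraction.  PEPs from
several score sources (engines, per-glycan searches) are combined by
summed -log10(PEP) re-ranking, spectra are sanitized to their single
best match, and peptidoform/protein q-values gate the final accepted
set together with spectral-count, glyco fragment-ion and replicate
rules.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .spectra import PSM, glyco_ion_evidence

PEP_FLOOR = 1e-6


@dataclass
class FilterConfig:
    """Thresholds of the identification filter cascade."""

    max_combined_pep: float = 0.01
    min_spectra_per_peptidoform: int = 2
    max_peptidoform_fdr: float = 0.01
    max_protein_fdr: float = 0.005
    min_glyco_B: int = 1
    min_glyco_Y: int = 2
    require_oxonium: bool = True
    min_replicates: int = 2

    def __post_init__(self):
        for p in (self.max_combined_pep, self.max_peptidoform_fdr, self.max_protein_fdr):
            if not (0 < p <= 1):
                raise ValueError("probability thresholds must be in (0, 1]")
        for c in (
            self.min_spectra_per_peptidoform,
            self.min_glyco_B,
            self.min_glyco_Y,
            self.min_replicates,
        ):
            if c < 1:
                raise ValueError("count thresholds must be >= 1")


def _isotonic_non_decreasing(values: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators fit: least-squares non-decreasing sequence."""
    level = list(values.astype(float))
    weight = [1.0] * len(level)
    blocks: list[tuple[float, float]] = []  # (mean, weight)
    for v, w in zip(level, weight):
        blocks.append((v, w))
        while len(blocks) > 1 and blocks[-2][0] > blocks[-1][0]:
            v2, w2 = blocks.pop()
            v1, w1 = blocks.pop()
            blocks.append(((v1 * w1 + v2 * w2) / (w1 + w2), w1 + w2))
    out = np.empty(len(level))
    i = 0
    for v, w in blocks:
        n = int(round(w))
        out[i : i + n] = v
        i += n
    return out


def estimate_pep(decoy_flags: Sequence[bool], window: int = 101) -> np.ndarray:
    """PEP per PSM from local decoy density down a score-ranked list.

    ``decoy_flags`` must be ordered best score first.  For each PSM the
    raw estimate is ``min(1, 2 * D_w / W)`` where ``D_w`` counts decoys
    in the centered rank window of ``W`` entries (truncated at the list
    edges); isotonic smoothing then enforces PEPs non-decreasing with
    worsening rank.  Lists shorter than the window fall back to a
    single whole-list window.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    flags = np.asarray(decoy_flags, dtype=float)
    n = flags.size
    if n == 0:
        return np.empty(0)
    if n < window:
        pep = min(1.0, 2.0 * flags.sum() / n)
        return np.full(n, pep)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(flags)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    raw = np.minimum(1.0, 2.0 * (csum[hi] - csum[lo]) / (hi - lo))
    return np.minimum(1.0, _isotonic_non_decreasing(raw))


def _effective_window(n: int, window: int) -> int:
    """Shrink the rank window on short lists so that a handful of
    low-scoring decoys cannot bleed PEP mass far up the ranking; about a
    tenth of the list, never below 31 entries, always odd."""
    w = min(window, max(31, n // 10))
    if w % 2 == 0:
        w -= 1
    return max(w, 3)


def assign_peps(
    psms: Sequence[PSM],
    engine: str,
    window: int = 101,
) -> None:
    """Rank PSMs by one engine's raw score and store per-PSM PEPs."""
    scored = [p for p in psms if engine in p.engine_scores]
    scored.sort(key=lambda p: (-p.engine_scores[engine], p.key))
    peps = estimate_pep(
        [p.is_decoy for p in scored], window=_effective_window(len(scored), window)
    )
    for psm, pep in zip(scored, peps):
        psm.engine_peps[engine] = float(pep)


def combined_score(engine_peps: Mapping[str, float]) -> float:
    """Summed -log10 PEP over engines; higher is better."""
    if not engine_peps:
        raise ValueError("no engine PEPs present")
    return sum(-math.log10(max(p, PEP_FLOOR)) for p in engine_peps.values())


def combine_peps(psms: Sequence[PSM], window: int = 101) -> None:
    """Combined PEP across engines and searches, stored on each PSM.

    PSMs are grouped by the exact set of engines that scored them;
    within each group PSMs are re-ranked by the summed -log10(PEP)
    score and the PEP is re-estimated from the local decoy density of
    that ranking.  A singleton group keeps its own (minimum) engine PEP.
    """
    groups: dict[frozenset[str], list[PSM]] = defaultdict(list)
    for p in psms:
        if not p.engine_peps:
            raise ValueError(f"PSM {p.spectrum_id} has no engine PEPs")
        groups[frozenset(p.engine_peps)].append(p)
    for members in groups.values():
        if len(members) == 1:
            members[0].combined_pep = min(members[0].engine_peps.values())
            continue
        members.sort(key=lambda p: (-combined_score(p.engine_peps), p.key))
        peps = estimate_pep(
            [p.is_decoy for p in members], window=_effective_window(len(members), window)
        )
        for psm, pep in zip(members, peps):
            psm.combined_pep = float(pep)


def resolve_candidate_tie(forms: Sequence["object"]):
    """Resolve a set of equally scored candidate peptidoforms.

    Identical keys are trivially resolved.  Placements of the same
    glycan set on the same (target/decoy) sequence fall back to the
    canonical N-X-S/T sequon prior; anything else — different glycan
    compositions, target-vs-decoy ties, or a tied prior — is genuinely
    ambiguous and returns ``None``.
    """
    keys = {f.key() for f in forms}
    if len(keys) == 1:
        return forms[0]
    signatures = {
        (f.sequence, tuple(sorted(g.name for _, g in f.glyco_mods)), f.is_decoy)
        for f in forms
    }
    if len(signatures) > 1:
        return None
    ranked = sorted(
        forms, key=lambda f: (-f.n_canonical_sequon_sites(), f.key())
    )
    if (
        ranked[0].n_canonical_sequon_sites()
        > ranked[1].n_canonical_sequon_sites()
    ):
        return ranked[0]
    return None


def sanitize(psms: Sequence[PSM]) -> list[PSM]:
    """One PSM per spectrum: best (lowest) combined PEP wins.  PEP ties
    (frequent, since the windowed estimator is granular) go to the
    higher raw engine score, then to the lexicographically smaller
    peptidoform string."""
    def rank(p: PSM) -> tuple:
        best_score = max(p.engine_scores.values()) if p.engine_scores else 0.0
        return (p.combined_pep, -best_score, p.key)

    by_spectrum: dict[str, list[PSM]] = defaultdict(list)
    for p in psms:
        by_spectrum[p.spectrum_id].append(p)
    out = []
    for sid in sorted(by_spectrum):
        ranked = sorted(by_spectrum[sid], key=rank)
        best = ranked[0]
        top = [p for p in ranked if rank(p)[:2] == rank(best)[:2]]
        # spectra that cannot distinguish their top matches — identical
        # PEP and raw score across searches, or an engine-level isobaric
        # tie carried on the PSM — are resolved by the sequon prior or
        # dropped as ambiguous
        if any(p.ambiguous for p in top):
            continue
        if len(top) > 1:
            resolved = resolve_candidate_tie([p.peptidoform for p in top])
            if resolved is None:
                continue
            best = next(p for p in top if p.peptidoform.key() == resolved.key())
        out.append(best)
    return out


def fdr_qvalues(decoy_flags: Sequence[bool]) -> np.ndarray:
    """Target-decoy q-values down a ranked list (best first).

    FDR at each rank is #decoys / #targets among entries at or above
    the rank (0 while no decoy has appeared); the q-value is the
    running minimum from the bottom, capped at 1.
    """
    flags = np.asarray(decoy_flags, dtype=bool)
    n = flags.size
    if n == 0:
        return np.empty(0)
    decoys = np.cumsum(flags)
    targets = np.cumsum(~flags)
    if targets[-1] == 0:
        raise ValueError("no target entries in ranking")
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(targets > 0, decoys / np.maximum(targets, 1), np.inf)
    fdr = np.minimum(fdr, 1.0)
    return np.minimum.accumulate(fdr[::-1])[::-1]


@dataclass
class PeptidoformGroup:
    """All surviving PSMs of one peptidoform."""

    key: str
    psms: list[PSM]
    is_decoy: bool
    q_value: float = 1.0

    @property
    def best_pep(self) -> float:
        return min(p.combined_pep for p in self.psms)

    @property
    def spectral_count(self) -> int:
        return len({p.spectrum_id for p in self.psms})

    @property
    def replicate_ids(self) -> set[str]:
        return {p.replicate_id for p in self.psms if p.replicate_id}

    @property
    def protein_id(self) -> str:
        return self.psms[0].peptidoform.span.protein_id

    @property
    def is_glyco(self) -> bool:
        return self.psms[0].peptidoform.is_glyco


@dataclass
class CascadeResult:
    """Accepted identifications plus per-stage survivor counts."""

    accepted_peptidoforms: list[PeptidoformGroup]
    accepted_glyco: list[PeptidoformGroup]
    stage_counts: dict[str, int]


def _group_by_peptidoform(psms: Iterable[PSM]) -> list[PeptidoformGroup]:
    grouped: dict[str, list[PSM]] = defaultdict(list)
    for p in psms:
        grouped[p.key].append(p)
    return [
        PeptidoformGroup(key, members, members[0].is_decoy)
        for key, members in sorted(grouped.items())
    ]


def apply_filter_cascade(
    psms: Sequence[PSM],
    cfg: FilterConfig | None = None,
) -> CascadeResult:
    """The full identification filter cascade.

    Stages, in order: (1) combined PEP <= threshold; (2) sanitization to
    one PSM per spectrum; (3) peptidoform q-value; (4) protein q-value;
    (5) minimum spectral count per peptidoform; (6) for glycopeptidoforms
    only, the glyco fragment-ion rule and the minimum-replicate rule.
    Decoys ride along through stages 1-2 (they drive the q-values) and
    are excluded from the accepted output.
    """
    cfg = cfg or FilterConfig()
    counts: dict[str, int] = {}

    stage1 = [p for p in psms if p.combined_pep <= cfg.max_combined_pep]
    counts["pep_filter"] = len(stage1)

    stage2 = sanitize(stage1)
    counts["sanitized"] = len(stage2)

    groups = _group_by_peptidoform(stage2)
    groups.sort(key=lambda g: (g.best_pep, g.key))
    if groups:
        qvals = fdr_qvalues([g.is_decoy for g in groups])
        for g, q in zip(groups, qvals):
            g.q_value = float(q)
    stage3 = [g for g in groups if g.q_value <= cfg.max_peptidoform_fdr]
    counts["peptidoform_fdr"] = sum(1 for g in stage3 if not g.is_decoy)

    # Protein level: each protein represented by its best peptidoform.
    by_protein: dict[tuple[str, bool], list[PeptidoformGroup]] = defaultdict(list)
    for g in stage3:
        by_protein[(g.protein_id, g.is_decoy)].append(g)
    proteins = sorted(
        by_protein.items(), key=lambda kv: (min(g.best_pep for g in kv[1]), kv[0][0])
    )
    protein_q: dict[tuple[str, bool], float] = {}
    if proteins:
        qvals = fdr_qvalues([is_decoy for (_, is_decoy), _ in proteins])
        for ((pid, is_decoy), _), q in zip(proteins, qvals):
            protein_q[(pid, is_decoy)] = float(q)
    stage4 = [
        g
        for g in stage3
        if protein_q[(g.protein_id, g.is_decoy)] <= cfg.max_protein_fdr
    ]
    counts["protein_fdr"] = sum(1 for g in stage4 if not g.is_decoy)

    stage5 = [
        g
        for g in stage4
        if not g.is_decoy and g.spectral_count >= cfg.min_spectra_per_peptidoform
    ]
    counts["min_spectra"] = len(stage5)

    accepted: list[PeptidoformGroup] = []
    accepted_glyco: list[PeptidoformGroup] = []
    for g in stage5:
        if not g.is_glyco:
            accepted.append(g)
            continue
        has_ions = glyco_ion_evidence(
            g.psms,
            require_oxonium=cfg.require_oxonium,
            min_B=cfg.min_glyco_B,
            min_Y=cfg.min_glyco_Y,
        )
        if has_ions and len(g.replicate_ids) >= cfg.min_replicates:
            accepted.append(g)
            accepted_glyco.append(g)
    counts["glyco_rules"] = len(accepted_glyco)
    counts["accepted"] = len(accepted)

    return CascadeResult(accepted, accepted_glyco, counts)
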