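"""End-to-end glycoproteomic search pipeline.

One run digests the proteome, enumerates target and decoy peptidoforms
for the unmodified search and one search per glycan composition,
scores every searchable spectrum against the candidates whose precursor
matches, estimates PEPs per search, combines them, and applies the
filter cascade per strain before glycosite mapping and strain
comparison.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem import DEFAULT_MODIFICATIONS, ModificationDef
from .digestion import (
    PROTEASES,
    Peptidoform,
    ProteaseRule,
    decoy_span,
    digest,
    enumerate_peptidoforms,
    read_fasta,
)
from .glycans import GlycanComposition, default_glycan_table
from .report import (
    GlycoproteomeSummary,
    GlycoSite,
    sites_from_peptidoforms,
    summarize,
)
from .spectra import PSM, Spectrum, match_peaks, read_mgf, theoretical_backbone_ions, theoretical_glyco_ions
from .stats import (
    CascadeResult,
    FilterConfig,
    assign_peps,
    combine_peps,
    apply_filter_cascade,
    resolve_candidate_tie,
)


@dataclass
class PipelineConfig:
    """Search and filter settings of one pipeline run."""

    protease: str = "trypsin"
    max_missed: int = 2
    precursor_ppm: float = 10.0
    backbone_frag_ppm: float = 10.0
    glyco_frag_ppm: float = 20.0
    glyco_frag_charges: tuple[int, ...] = (1, 2)
    max_variable_mods: int = 1
    max_glyco_sites: int = 2
    min_peptide_len: int = 6
    max_peptide_len: int = 40
    acquisition_min_mz: float = 130.0
    pep_window: int = 101
    decoy_seed: int = 1
    modifications: tuple[ModificationDef, ...] = DEFAULT_MODIFICATIONS
    glycans: tuple[GlycanComposition, ...] = field(
        default_factory=lambda: tuple(default_glycan_table())
    )
    filters: FilterConfig = field(default_factory=FilterConfig)

    @property
    def protease_rule(self) -> ProteaseRule:
        return PROTEASES[self.protease]


@dataclass
class SearchSpace:
    """Candidate peptidoforms of one search, indexed by neutral mass."""

    name: str
    forms: list[Peptidoform]
    masses: np.ndarray  # sorted

    def candidates(self, neutral_mass: float, ppm: float) -> list[Peptidoform]:
        delta = neutral_mass * ppm * 1e-6
        lo = int(np.searchsorted(self.masses, neutral_mass - delta, side="left"))
        hi = int(np.searchsorted(self.masses, neutral_mass + delta, side="right"))
        return self.forms[lo:hi]


def build_search_spaces(
    proteome: dict[str, str],
    config: PipelineConfig,
) -> list[SearchSpace]:
    """Digest the proteome and enumerate candidates for the unmodified
    search and one search per glycan (engines handle one glycan type at
    a time).  Decoys come from a shuffled-peptide decoy database built
    from the same digest."""
    spans = []
    for pid in sorted(proteome):
        for span in digest(pid, proteome[pid], config.protease_rule, config.max_missed):
            if config.min_peptide_len <= len(span.sequence) <= config.max_peptide_len:
                spans.append(span)
    decoy_spans = [decoy_span(s, seed=config.decoy_seed) for s in spans]

    searches: list[tuple[str, GlycanComposition | None]] = [("unmodified", None)]
    searches += [(g.name, g) for g in config.glycans]

    spaces = []
    seen_global: set[str] = set()
    for name, glycan in searches:
        forms: dict[str, Peptidoform] = {}
        for span_list, is_decoy in ((spans, False), (decoy_spans, True)):
            for span in span_list:
                if glycan is not None and not any(
                    t in span.sequence for t in glycan.target_residues
                ):
                    continue
                for form in enumerate_peptidoforms(
                    span,
                    glycan=glycan,
                    max_variable=config.max_variable_mods,
                    max_glyco_sites=config.max_glyco_sites,
                    modifications=config.modifications,
                    glyco_only=glycan is not None,
                    is_decoy=is_decoy,
                ):
                    key = form.key()
                    # shared peptides keep their first (sorted) protein
                    if key not in forms and key not in seen_global:
                        forms[key] = form
        all_forms = [forms[k] for k in sorted(forms)]
        seen_global.update(forms)
        all_forms.sort(key=lambda f: f.neutral_mass)
        spaces.append(
            SearchSpace(name, all_forms, np.array([f.neutral_mass for f in all_forms]))
        )
    return spaces


def search_spectra(
    spectra: Sequence[Spectrum],
    spaces: Sequence[SearchSpace],
    config: PipelineConfig,
) -> list[PSM]:
    """Score spectra against every search; keep the best-scoring
    candidate (target or decoy) per spectrum per search, then estimate
    per-search PEPs and the combined PEP."""
    psms: list[PSM] = []
    engine = "naive"
    theo_cache: dict[int, list[tuple[str, float]]] = {}
    for space in spaces:
        for s in spectra:
            if not s.searchable:
                continue
            best_forms: list[Peptidoform] = []
            best_score = 0.0
            neutral = s.precursor_neutral_mass
            total = float(s.intensity.sum())
            for form in space.candidates(neutral, config.precursor_ppm):
                theo = theo_cache.get(id(form))
                if theo is None:
                    theo = theoretical_backbone_ions(form, max_frag_charge=1)
                    theo_cache[id(form)] = theo
                res = match_peaks(s, theo, config.backbone_frag_ppm)
                if not res.matched_peak_indices:
                    continue
                peak_idx = sorted(set(res.matched_peak_indices))
                matched = float(s.intensity[peak_idx].sum())
                score = len(peak_idx) * float(np.log1p(matched / total))
                if score > best_score:
                    best_forms, best_score = [form], score
                elif score == best_score and best_forms:
                    best_forms.append(form)
            if not best_forms:
                continue
            # equally scored candidates (isobaric placements with no
            # site-determining peak) resolve by the sequon prior; an
            # unresolved tie is carried forward as an ambiguous PSM so
            # that sanitization can discard the whole spectrum, also
            # against isobaric competitors from other searches
            best_form = resolve_candidate_tie(best_forms)
            ambiguous = best_form is None
            if ambiguous:
                best_form = min(best_forms, key=lambda f: f.key())
            psm = PSM(
                spectrum_id=s.spectrum_id,
                peptidoform=best_form,
                engine_scores={engine: best_score},
                replicate_id=s.replicate_id,
                fraction_id=s.fraction_id,
                strain_id=s.strain_id,
                ambiguous=ambiguous,
            )
            if best_form.is_glyco:
                glyco_theo = theoretical_glyco_ions(
                    best_form,
                    charges=config.glyco_frag_charges,
                    min_mz=config.acquisition_min_mz,
                )
                psm.glyco_evidence = match_peaks(s, glyco_theo, config.glyco_frag_ppm)
            psms.append(psm)
    # The naive engine's raw score is comparable across per-glycan
    # searches, so its PEP is estimated on the pooled ranking.
    assign_peps(psms, engine, window=config.pep_window)
    combine_peps(psms, window=config.pep_window)
    return psms


@dataclass
class StrainResult:
    strain: str
    psms: list[PSM]
    cascade: CascadeResult
    sites: list[GlycoSite]


@dataclass
class PipelineResult:
    per_strain: dict[str, StrainResult]
    summary: GlycoproteomeSummary

    @property
    def pooled_sites(self) -> list[GlycoSite]:
        out = []
        for r in self.per_strain.values():
            out.extend(r.sites)
        return out


def run_pipeline(
    proteome: dict[str, str],
    spectra: Sequence[Spectrum],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Full analysis: per-strain search (replicates and fractions are
    merged before statistics), filter cascade, glycosite mapping, and a
    cross-strain summary."""
    config = config or PipelineConfig()
    spaces = build_search_spaces(proteome, config)

    by_strain: dict[str, list[Spectrum]] = defaultdict(list)
    for s in spectra:
        by_strain[s.strain_id or ""].append(s)

    per_strain: dict[str, StrainResult] = {}
    accepted_glyco_all = []
    for strain in sorted(by_strain):
        psms = search_spectra(by_strain[strain], spaces, config)
        cascade = apply_filter_cascade(psms, config.filters)
        sites = sites_from_peptidoforms(cascade.accepted_glyco, proteome)
        per_strain[strain] = StrainResult(strain, psms, cascade, sites)
        accepted_glyco_all.extend(cascade.accepted_glyco)

    pooled_sites = sites_from_peptidoforms(accepted_glyco_all, proteome)
    summary = summarize(pooled_sites, accepted_glyco_all)
    return PipelineResult(per_strain, summary)


def run_from_files(
    fasta_path: str | Path,
    mgf_paths: Sequence[str | Path],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    proteome = read_fasta(fasta_path)
    spectra: list[Spectrum] = []
    for path in mgf_paths:
        spectra.extend(read_mgf(path))
    return run_pipeline(proteome, spectra, config)


PSM_TABLE_COLUMNS = [
    "spectrum_id", "strain", "replicate", "fraction", "protein_id", "start",
    "end", "peptidoform", "is_decoy", "ambiguous", "combined_pep",
    "engine_scores", "glyco_Y", "glyco_B",
]


def write_psm_table(psms: Sequence[PSM], path: str | Path) -> None:
    """PSM table as TSV with a stable column set; m/z-free, key-based."""
    lines = ["\t".join(PSM_TABLE_COLUMNS)]
    for p in psms:
        span = p.peptidoform.span
        ev = p.glyco_evidence
        lines.append(
            "\t".join(
                [
                    p.spectrum_id,
                    p.strain_id,
                    p.replicate_id,
                    p.fraction_id,
                    span.protein_id,
                    str(span.start),
                    str(span.end),
                    p.key,
                    str(p.is_decoy),
                    str(p.ambiguous),
                    f"{p.combined_pep:.6g}",
                    json.dumps(p.engine_scores, sort_keys=True),
                    str(ev.distinct_glyco_Y if ev else 0),
                    str(ev.distinct_glyco_B if ev else 0),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_peptidoform(
    key: str,
    protein_id: str,
    start: int,
    end: int,
    config: PipelineConfig,
    is_decoy: bool,
) -> Peptidoform:
    from .digestion import PeptideSpan

    glycan_by_name = {g.name: g for g in config.glycans}
    mod_by_name = {m.name: m for m in config.modifications}
    body = key.removeprefix("decoy_")
    if "[" in body:
        seq, tag = body[:-1].split("[", 1)
        mods = [t.rsplit("@", 1) for t in tag.split(";") if t]
    else:
        seq, mods = body, []
    span = PeptideSpan(protein_id, start, end, seq)
    fixed, variable, glyco = [], [], []
    for name, pos in mods:
        pos = int(pos)
        if name in glycan_by_name:
            glyco.append((pos, glycan_by_name[name]))
        else:
            mod = mod_by_name[name]
            (fixed if mod.fixed else variable).append((pos, mod))
    return Peptidoform(
        span,
        fixed_mods=tuple(fixed),
        variable_mods=tuple(variable),
        glyco_mods=tuple(sorted(glyco)),
        is_decoy=is_decoy,
    )


def read_psm_table(
    path: str | Path,
    config: PipelineConfig | None = None,
) -> list[PSM]:
    """Read back a table written by :func:`write_psm_table`."""
    from .spectra import FragmentMatchResult

    config = config or PipelineConfig()
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    psms = []
    for line in lines[1:]:
        if not line.strip():
            continue
        row = dict(zip(header, line.split("\t")))
        form = _parse_peptidoform(
            row["peptidoform"],
            row["protein_id"],
            int(row["start"]),
            int(row["end"]),
            config,
            row["is_decoy"] == "True",
        )
        psm = PSM(
            spectrum_id=row["spectrum_id"],
            peptidoform=form,
            engine_scores=json.loads(row["engine_scores"]),
            combined_pep=float(row["combined_pep"]),
            replicate_id=row["replicate"],
            fraction_id=row["fraction"],
            strain_id=row["strain"],
            ambiguous=row.get("ambiguous", "False") == "True",
        )
        n_y, n_b = int(row["glyco_Y"]), int(row["glyco_B"])
        if form.is_glyco:
            # reconstruct distinct-rung counts for the evidence rule
            labels = [f"Y{k}+1" for k in range(n_y)] + [f"B{k + 1}+1" for k in range(n_b)]
            psm.glyco_evidence = FragmentMatchResult(
                matched_glyco_Y=n_y, matched_glyco_B=n_b, matched_labels=labels
            )
        psms.append(psm)
    return psms


def read_engine_psms(
    path: str | Path,
    proteome: dict[str, str],
    config: PipelineConfig | None = None,
) -> list[PSM]:
    """External engine adapter: read PSMs from the TSV contract
    (spectrum_id, protein_id, start, end, peptidoform, score,
    engine, pep, is_decoy) so real engine output can replace the naive
    engine.  ``pep`` may be empty; it is then estimated downstream."""
    config = config or PipelineConfig()
    psms = []
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        if not line.strip():
            continue
        row = dict(zip(header, line.split("\t")))
        key = row["peptidoform"]
        is_decoy = row.get("is_decoy", "False") == "True" or key.startswith("decoy_")
        form = _parse_peptidoform(
            key, row["protein_id"], int(row["start"]), int(row["end"]), config, is_decoy
        )
        engine = row.get("engine", "external")
        psm = PSM(
            spectrum_id=row["spectrum_id"],
            peptidoform=form,
            engine_scores={engine: float(row["score"])},
        )
        if row.get("pep"):
            psm.engine_peps[engine] = float(row["pep"])
        psms.append(psm)
    return psms
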