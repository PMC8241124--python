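"""Glycosite mapping, sequon classification, glycoproteome aggregation
and strain comparison.

Accepted glycopeptidoforms are projected onto protein coordinates
(1-based on the full translated sequence), merged by (protein,
position), classified against the canonical N-X-S/T sequon, and
aggregated into per-strain and pooled summaries with overlap sets.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .glycans import Pathway
from .stats import PeptidoformGroup


@dataclass
class GlycoSite:
    """An observed glycosylation site on a protein."""

    protein_id: str
    position: int  # 1-based on the full protein
    residue: str
    pathways_observed: set[Pathway] = field(default_factory=set)
    sequon_class: str = "noncanonical"
    psm_count: int = 0
    replicate_ids: set[str] = field(default_factory=set)
    datasets: set[str] = field(default_factory=set)
    glycans_observed: set[str] = field(default_factory=set)
    ambiguous: bool = False


def classify_sequon(
    protein_seq: str,
    position: int,
    strict: bool = False,
) -> str:
    """Classify an N residue against the N-X-S/T sequon.

    ``position`` is 1-based; the residue there must be N.  Canonical
    means a residue exists two positions downstream and is S or T; X is
    unrestricted by default, while ``strict`` additionally excludes
    X = P (the eukaryotic convention).
    """
    if protein_seq[position - 1] != "N":
        raise ValueError(
            f"residue at position {position} is {protein_seq[position - 1]!r}, not N"
        )
    if position + 2 > len(protein_seq):
        return "noncanonical"
    if strict and protein_seq[position] == "P":
        return "noncanonical"
    return "canonical" if protein_seq[position + 1] in "ST" else "noncanonical"


def sites_from_peptidoforms(
    accepted_glyco: Sequence[PeptidoformGroup],
    proteome: Mapping[str, str],
    strict_sequon: bool = False,
) -> list[GlycoSite]:
    """Project accepted glycopeptidoforms onto protein glycosites.

    Site position = span start + in-peptide position - 1; sites observed
    through several peptidoforms are merged, with pathways, glycans,
    replicates and PSM counts aggregated.
    """
    merged: dict[tuple[str, int], GlycoSite] = {}
    for group in accepted_glyco:
        form = group.psms[0].peptidoform
        span = form.span
        protein_seq = proteome.get(span.protein_id)
        if protein_seq is None:
            raise ValueError(f"protein {span.protein_id!r} absent from proteome")
        if protein_seq[span.start - 1 : span.end] != span.sequence:
            raise ValueError(
                f"span {span.start}-{span.end} does not match protein {span.protein_id}"
            )
        datasets = {p.strain_id for p in group.psms if p.strain_id}
        for in_peptide_pos, glycan in form.glyco_mods:
            position = span.start + in_peptide_pos - 1
            residue = protein_seq[position - 1]
            site = merged.get((span.protein_id, position))
            if site is None:
                if glycan.pathway is Pathway.O_linked:
                    sequon_class = "o_linked"
                else:
                    sequon_class = classify_sequon(
                        protein_seq, position, strict=strict_sequon
                    )
                site = GlycoSite(
                    span.protein_id, position, residue, sequon_class=sequon_class
                )
                merged[(span.protein_id, position)] = site
            site.pathways_observed.add(glycan.pathway)
            site.glycans_observed.add(glycan.name)
            site.psm_count += group.spectral_count
            site.replicate_ids |= group.replicate_ids
            site.datasets |= datasets
    return [merged[k] for k in sorted(merged)]


@dataclass
class GlycoproteomeSummary:
    """Pooled and per-strain glycoproteome counts and overlap sets."""

    n_glycopeptidoforms: int
    n_glycosites: int
    n_glycoproteins: int
    per_pathway_peptidoforms: dict[str, int]
    strain_peptidoforms: dict[str, set[str]]
    strain_proteins: dict[str, set[str]]
    peptidoform_overlap: dict[tuple[str, ...], set[str]]
    protein_overlap: dict[tuple[str, ...], set[str]]


def _overlaps(sets: Mapping[str, set[str]]) -> dict[tuple[str, ...], set[str]]:
    """All pairwise and higher-order intersections of the labeled sets."""
    from itertools import combinations

    labels = sorted(sets)
    out: dict[tuple[str, ...], set[str]] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inter = set(sets[combo[0]])
            for label in combo[1:]:
                inter &= sets[label]
            out[combo] = inter
    return out


def summarize(
    sites: Sequence[GlycoSite],
    accepted_glyco: Sequence[PeptidoformGroup],
) -> GlycoproteomeSummary:
    """Aggregate accepted glycopeptidoforms and sites per strain.

    A peptidoform is attributed to every strain contributing an
    accepted PSM; overlap sets are exact intersections, so counts obey
    inclusion-exclusion by construction.
    """
    strain_forms: dict[str, set[str]] = defaultdict(set)
    strain_proteins: dict[str, set[str]] = defaultdict(set)
    per_pathway: dict[str, int] = defaultdict(int)
    for group in accepted_glyco:
        pathways = {g.pathway.value for _, g in group.psms[0].peptidoform.glyco_mods}
        for pw in pathways:
            per_pathway[pw] += 1
        strains = {p.strain_id for p in group.psms if p.strain_id} or {""}
        for strain in strains:
            strain_forms[strain].add(group.key)
            strain_proteins[strain].add(group.protein_id)
    return GlycoproteomeSummary(
        n_glycopeptidoforms=len({g.key for g in accepted_glyco}),
        n_glycosites=len(sites),
        n_glycoproteins=len({s.protein_id for s in sites}),
        per_pathway_peptidoforms=dict(per_pathway),
        strain_peptidoforms=dict(strain_forms),
        strain_proteins=dict(strain_proteins),
        peptidoform_overlap=_overlaps(strain_forms),
        protein_overlap=_overlaps(strain_proteins),
    )


def percentage_increase(single: int, combined: int) -> int:
    """Relative gain of a combined analysis over a single one, as the
    nearest integer percentage."""
    if single <= 0:
        raise ValueError("baseline count must be positive")
    return round((combined - single) / single * 100)


def coverage_percent(identified: int, theoretical: int, ndigits: int = 1) -> float:
    """Identified fraction of a theoretical proteome, in percent."""
    if theoretical <= 0:
        raise ValueError("theoretical proteome size must be positive")
    return round(identified / theoretical * 100, ndigits)


def apply_position_offsets(
    sites: Iterable[GlycoSite],
    offsets: Mapping[str, int],
) -> dict[tuple[str, int], int]:
    """Mature-protein numbering: reported position = raw - offset.

    ``offsets`` maps protein_id to the signal-peptide length; proteins
    without an entry keep their raw coordinates.
    """
    return {
        (s.protein_id, s.position): s.position - offsets.get(s.protein_id, 0)
        for s in sites
    }


def write_glycosites_tsv(
    sites: Sequence[GlycoSite],
    path: str | Path,
    offsets: Mapping[str, int] | None = None,
) -> None:
    mature = apply_position_offsets(sites, offsets or {})
    lines = [
        "protein_id\tposition\tmature_position\tresidue\tsequon_class\t"
        "pathways\tglycans\tpsm_count\treplicates\tdatasets"
    ]
    for s in sites:
        lines.append(
            "\t".join(
                [
                    s.protein_id,
                    str(s.position),
                    str(mature[(s.protein_id, s.position)]),
                    s.residue,
                    s.sequon_class,
                    ",".join(sorted(p.value for p in s.pathways_observed)),
                    ",".join(sorted(s.glycans_observed)),
                    str(s.psm_count),
                    ",".join(sorted(s.replicate_ids)),
                    ",".join(sorted(s.datasets)),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_glycoproteins_tsv(sites: Sequence[GlycoSite], path: str | Path) -> None:
    by_protein: dict[str, list[GlycoSite]] = defaultdict(list)
    for s in sites:
        by_protein[s.protein_id].append(s)
    lines = ["protein_id\tn_sites\tpositions\tpathways"]
    for pid in sorted(by_protein):
        plist = by_protein[pid]
        pathways = sorted({p.value for s in plist for p in s.pathways_observed})
        lines.append(
            f"{pid}\t{len(plist)}\t"
            f"{','.join(str(s.position) for s in sorted(plist, key=lambda x: x.position))}\t"
            f"{','.join(pathways)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_overlap_tsv(summary: GlycoproteomeSummary, path: str | Path) -> None:
    lines = ["level\tstrains\tn_items"]
    for combo in sorted(summary.peptidoform_overlap):
        lines.append(
            f"glycopeptidoform\t{'&'.join(combo)}\t{len(summary.peptidoform_overlap[combo])}"
        )
    for combo in sorted(summary.protein_overlap):
        lines.append(
            f"glycoprotein\t{'&'.join(combo)}\t{len(summary.protein_overlap[combo])}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
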