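"""Ground-truthed synthetic proteomes and MS2 data.

The generator emulates the structure of a fractionated glycoproteomic
experiment on a halophilic archaeon: a small proteome of secreted and
cytosolic proteins; N-glycosylation sequons planted in secreted
proteins and glycosylated through two pathways (AglB-type, dominant;
Agl15-type, minor) plus a rare O-linked disaccharide; three strains
(wild type and one deletion strain per N-pathway, each lacking that
pathway's glycans entirely); membrane/cytosol/supernatant fractions and
two replicates per strain.  Fragment spectra are Bernoulli-thinned
theoretical b/y and glyco Y/B peak sets with ppm jitter, log-normal
intensities and uniform noise peaks, within a 130-2000 m/z acquisition
window; precursors are restricted to charges 2-4 inside a 400-2000 m/z
survey range.  Every spectrum, peptidoform and site is recorded in
truth tables so recall and false-discovery proportion can be measured
exactly.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem import DEFAULT_MODIFICATIONS, mz_from_mass
from .digestion import (
    PeptideSpan,
    Peptidoform,
    TRYPSIN,
    digest,
    eligible_positions,
    write_fasta,
)
from .glycans import GlycanComposition, Pathway, default_glycan_table
from .spectra import (
    Spectrum,
    theoretical_backbone_ions,
    theoretical_glyco_ions,
    write_mgf,
)

# Background amino-acid frequencies, tuned so tryptic peptides average
# roughly 9 residues (K+R ~ 11%).
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_WEIGHTS = np.array(
    [0.08, 0.01, 0.05, 0.07, 0.04, 0.07, 0.02, 0.05, 0.06, 0.09,
     0.02, 0.04, 0.04, 0.04, 0.05, 0.07, 0.06, 0.07, 0.01, 0.03]
)
_AA_WEIGHTS = _AA_WEIGHTS / _AA_WEIGHTS.sum()


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    n_proteins: int = 50
    protein_length: tuple[int, int] = (120, 600)
    fraction_secreted: float = 0.6
    sequon_per_100aa: float = 0.7
    noncanonical_fraction: float = 0.1
    p_site_glycosylated: float = 0.5
    pathway_mix: dict[str, float] = field(
        default_factory=lambda: {"AglB": 0.85, "Agl15": 0.10, "O_linked": 0.05}
    )
    p_full_glycan: float = 0.6
    strains: dict[str, frozenset[str]] = field(
        default_factory=lambda: {
            "WT": frozenset(),
            "dagl15": frozenset({"Agl15"}),
            "daglB": frozenset({"AglB"}),
        }
    )
    n_dual_pathway_sites: int = 2
    n_replicates: int = 2
    fractions: tuple[str, ...] = ("Mem", "Cyt", "SN")
    n_background_peptides: int = 80
    p_detect_backbone: float = 0.7
    p_detect_glyco: float = 0.8
    n_noise_peaks: int = 30
    noise_mz_range: tuple[float, float] = (130.0, 2000.0)
    noise_spectrum_rate: float = 0.15
    intensity_mu: float = 10.0
    intensity_sigma: float = 1.0
    noise_intensity_mu: float = 8.5
    ppm_jitter: float = 3.0
    precursor_charges: tuple[int, ...] = (2, 3, 4)
    ms1_range: tuple[float, float] = (400.0, 2000.0)
    ms2_range: tuple[float, float] = (130.0, 2000.0)
    max_missed: int = 2
    min_peptide_len: int = 6
    max_peptide_len: int = 40
    max_spectra_per_form: int = 6

    def __post_init__(self):
        total = sum(self.pathway_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("pathway_mix must sum to 1")
        for p in (
            self.fraction_secreted,
            self.p_site_glycosylated,
            self.p_detect_backbone,
            self.p_detect_glyco,
            self.noise_spectrum_rate,
            self.noncanonical_fraction,
        ):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.noise_mz_range
        if lo < self.ms2_range[0] or hi > self.ms2_range[1]:
            raise ValueError("noise m/z range must lie within the acquisition window")


@dataclass
class PlantedSite:
    protein_id: str
    position: int  # 1-based
    residue: str
    canonical: bool
    secreted: bool
    glycosylated: bool = False
    pathway: str | None = None
    glycan: str | None = None


@dataclass
class PlantedForm:
    """One peptidoform planted in one strain's sample."""

    strain: str
    form: Peptidoform
    pathway: str | None
    site_positions: tuple[int, ...]  # protein coordinates
    n_spectra: int = 0
    replicate_ids: set[str] = field(default_factory=set)

    @property
    def eligible(self) -> bool:
        """Can pass the >=2 spectra and >=2 replicate rules."""
        return self.n_spectra >= 2 and len(self.replicate_ids) >= 2


@dataclass
class GroundTruth:
    """Everything the generator planted, for exact scoring of a run."""

    spectrum_truth: dict[str, str | None]  # spectrum_id -> peptidoform key / None
    planted_forms: list[PlantedForm]
    sites: list[PlantedSite]

    def eligible_glyco_keys(self, strain: str) -> set[str]:
        return {
            pf.form.key()
            for pf in self.planted_forms
            if pf.strain == strain and pf.form.is_glyco and pf.eligible
        }

    def planted_glyco_keys(self, strain: str) -> set[str]:
        return {
            pf.form.key()
            for pf in self.planted_forms
            if pf.strain == strain and pf.form.is_glyco
        }


def _glycans_by_pathway() -> dict[str, list[GlycanComposition]]:
    table = default_glycan_table()
    out: dict[str, list[GlycanComposition]] = defaultdict(list)
    for g in table:
        out[g.pathway.value].append(g)
    return out


def generate_proteome(
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], list[PlantedSite]]:
    """Random proteome with planted sequons; deterministic under seed.

    Secreted proteins receive canonical N-X-S/T sequons at the target
    density plus a small quota of noncanonical N sites; cytosolic
    proteins stay sequon-free so that localization structure mirrors a
    secretory N-glycosylation system.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    proteins: dict[str, str] = {}
    sites: list[PlantedSite] = []
    n_secreted = round(cfg.n_proteins * cfg.fraction_secreted)
    for i in range(cfg.n_proteins):
        pid = f"P{i:03d}"
        secreted = i < n_secreted
        length = int(rng.integers(cfg.protein_length[0], cfg.protein_length[1] + 1))
        seq = list(rng.choice(list(_AA), size=length, p=_AA_WEIGHTS))
        if secreted:
            # disrupt accidental N-X-S/T so sequon density is an exact
            # control, then plant sequons deliberately
            for j in range(length - 2):
                if seq[j] == "N" and seq[j + 2] in "ST":
                    seq[j] = "Q"
            n_sites = max(0, round(length * cfg.sequon_per_100aa / 100))
            positions: list[int] = []
            attempts = 0
            while len(positions) < n_sites and attempts < 200:
                attempts += 1
                pos = int(rng.integers(10, length - 10))
                if all(abs(pos - q) >= 15 for q in positions):
                    positions.append(pos)
            for pos in sorted(positions):
                canonical = bool(rng.random() >= cfg.noncanonical_fraction)
                seq[pos - 1] = "N"
                x = _AA[int(rng.integers(len(_AA)))]
                while x in "PC":
                    x = _AA[int(rng.integers(len(_AA)))]
                seq[pos] = x
                if canonical:
                    seq[pos + 1] = "S" if rng.random() < 0.5 else "T"
                else:
                    y = _AA[int(rng.integers(len(_AA)))]
                    while y in "STC":
                        y = _AA[int(rng.integers(len(_AA)))]
                    seq[pos + 1] = y
                sites.append(PlantedSite(pid, pos, "N", canonical, secreted))
        proteins[pid] = "".join(seq)
    return proteins, sites


def _assign_glycans(
    cfg: GeneratorConfig,
    sites: list[PlantedSite],
    rng: np.random.Generator,
) -> None:
    """Mark sites as glycosylated and draw pathway and glycan."""
    by_pathway = _glycans_by_pathway()
    pathways = sorted(cfg.pathway_mix)
    probs = np.array([cfg.pathway_mix[p] for p in pathways])
    for site in sites:
        if not site.secreted or rng.random() >= cfg.p_site_glycosylated:
            continue
        pathway = pathways[int(rng.choice(len(pathways), p=probs))]
        if pathway == "O_linked" and not site.canonical:
            # the O-glycan rides the sequon's +2 S/T; noncanonical sites
            # have none, so fall back to the dominant pathway
            pathway = "AglB"
        site.glycosylated = True
        site.pathway = pathway
        options = by_pathway[pathway]
        if rng.random() < cfg.p_full_glycan:
            glycan = max(options, key=len)
        else:
            glycan = options[int(rng.integers(len(options)))]
        site.glycan = glycan.name


def _covering_span(
    protein_id: str,
    sequence: str,
    position: int,
    cfg: GeneratorConfig,
) -> PeptideSpan | None:
    """Smallest fully-tryptic span covering a site within length limits."""
    spans = digest(protein_id, sequence, TRYPSIN, cfg.max_missed)
    covering = [
        s
        for s in spans
        if s.start <= position <= s.end
        and cfg.min_peptide_len <= len(s.sequence) <= cfg.max_peptide_len
    ]
    if not covering:
        return None
    covering.sort(key=lambda s: (s.missed_cleavages, len(s.sequence)))
    return covering[0]


def _feasible_charges(mass: float, cfg: GeneratorConfig) -> list[int]:
    lo, hi = cfg.ms1_range
    return [z for z in cfg.precursor_charges if lo <= mz_from_mass(mass, z) <= hi]


def _build_planted_forms(
    cfg: GeneratorConfig,
    proteins: dict[str, str],
    sites: list[PlantedSite],
    rng: np.random.Generator,
) -> list[PlantedForm]:
    glycan_by_name = {g.name: g for g in default_glycan_table()}
    by_pathway = _glycans_by_pathway()

    # Dual-pathway feature: a few AglB sites also seen with an Agl15
    # glycan (in strains where both pathways are active).
    aglb_sites = [s for s in sites if s.glycosylated and s.pathway == "AglB"]
    dual = set()
    if aglb_sites and cfg.n_dual_pathway_sites:
        chosen = rng.choice(
            len(aglb_sites), size=min(cfg.n_dual_pathway_sites, len(aglb_sites)),
            replace=False,
        )
        dual = {(aglb_sites[i].protein_id, aglb_sites[i].position) for i in chosen}

    forms: list[PlantedForm] = []
    for strain in sorted(cfg.strains):
        disabled = cfg.strains[strain]
        # glyco forms: group glycosylated sites by covering span
        span_groups: dict[tuple, list[tuple[PlantedSite, GlycanComposition]]] = (
            defaultdict(list)
        )
        for site in sites:
            if not site.glycosylated or site.pathway in disabled:
                continue
            span = _covering_span(
                site.protein_id, proteins[site.protein_id], site.position, cfg
            )
            if span is None:
                continue
            glycan = glycan_by_name[site.glycan]
            key = (span.protein_id, span.start, span.end)
            span_groups[key].append((site, glycan))
            if (
                (site.protein_id, site.position) in dual
                and "Agl15" not in disabled
            ):
                alt = max(by_pathway["Agl15"], key=len)
                span_groups[key].append((site, alt))
        for key in sorted(span_groups):
            entries = span_groups[key]
            span = _covering_span(
                entries[0][0].protein_id,
                proteins[entries[0][0].protein_id],
                entries[0][0].position,
                cfg,
            )
            # one planted form per glycan name present on the span (1 or 2 sites)
            per_glycan: dict[str, list[PlantedSite]] = defaultdict(list)
            for site, glycan in entries:
                per_glycan[glycan.name].append(site)
            for gname in sorted(per_glycan):
                glycan = glycan_by_name[gname]
                site_list = per_glycan[gname][:2]  # engines place at most 2
                glyco_mods = []
                ok = True
                for site in site_list:
                    in_pep = site.position - span.start + 1
                    target_pos = in_pep
                    if glycan.pathway is Pathway.O_linked:
                        # O-glycan on the sequon's +2 S/T
                        target_pos = in_pep + 2
                        if (
                            target_pos > len(span.sequence)
                            or span.sequence[target_pos - 1] not in "ST"
                        ):
                            ok = False
                            break
                    glyco_mods.append((target_pos, glycan))
                if not ok:
                    continue
                fixed = tuple(
                    (pos, mod)
                    for mod in DEFAULT_MODIFICATIONS
                    if mod.fixed
                    for pos in eligible_positions(span.sequence, mod.target)
                )
                taken = {p for p, _ in fixed}
                glyco_mods = tuple(
                    (p, g) for p, g in sorted(glyco_mods) if p not in taken
                )
                if not glyco_mods:
                    continue
                form = Peptidoform(span, fixed_mods=fixed, glyco_mods=glyco_mods)
                if not _feasible_charges(form.neutral_mass, cfg):
                    continue
                forms.append(
                    PlantedForm(
                        strain,
                        form,
                        glycan.pathway.value,
                        tuple(span.start + p - 1 for p, _ in glyco_mods),
                    )
                )

        # background non-glyco peptidoforms, shared across strains
        bg_rng = np.random.default_rng(cfg.seed + 7)
        all_spans = []
        for pid in sorted(proteins):
            for s in digest(pid, proteins[pid], TRYPSIN, 0):
                if cfg.min_peptide_len <= len(s.sequence) <= 25:
                    all_spans.append(s)
        n_bg = min(cfg.n_background_peptides, len(all_spans))
        for idx in bg_rng.choice(len(all_spans), size=n_bg, replace=False):
            span = all_spans[int(idx)]
            fixed = tuple(
                (pos, mod)
                for mod in DEFAULT_MODIFICATIONS
                if mod.fixed
                for pos in eligible_positions(span.sequence, mod.target)
            )
            form = Peptidoform(span, fixed_mods=fixed)
            if not _feasible_charges(form.neutral_mass, cfg):
                continue
            forms.append(PlantedForm(strain, form, None, ()))
    return forms


def simulate_spectrum(
    p: Peptidoform,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    spectrum_id: str = "sim.1",
    strain: str = "",
    replicate: str = "",
    fraction: str = "",
) -> Spectrum:
    """One synthetic MS2 spectrum of a peptidoform.

    Theoretical backbone b/y peaks (with and without the labile glycan)
    and glyco Y/B peaks are kept with the configured detection
    probabilities, jittered in ppm and given log-normal intensities;
    uniform noise peaks are added and everything is clipped to the
    acquisition window.
    """
    charges = _feasible_charges(p.neutral_mass, cfg)
    if not charges:
        raise ValueError("no allowed precursor charge puts the peptide in range")
    z = charges[int(rng.integers(len(charges)))]
    precursor = mz_from_mass(p.neutral_mass, z) * (
        1 + rng.normal(0, cfg.ppm_jitter) * 1e-6
    )

    mzs: list[float] = []
    intens: list[float] = []
    lo, hi = cfg.ms2_range
    for _, mz in theoretical_backbone_ions(p, max_frag_charge=1):
        if lo <= mz <= hi and rng.random() < cfg.p_detect_backbone:
            mzs.append(mz * (1 + rng.normal(0, cfg.ppm_jitter) * 1e-6))
            intens.append(rng.lognormal(cfg.intensity_mu, cfg.intensity_sigma))
    if p.is_glyco:
        for _, mz in theoretical_glyco_ions(p, charges=(1, 2)):
            if lo <= mz <= hi and rng.random() < cfg.p_detect_glyco:
                mzs.append(mz * (1 + rng.normal(0, cfg.ppm_jitter) * 1e-6))
                intens.append(rng.lognormal(cfg.intensity_mu, cfg.intensity_sigma))
    n_noise = cfg.n_noise_peaks
    if n_noise:
        noise_mz = rng.uniform(cfg.noise_mz_range[0], cfg.noise_mz_range[1], n_noise)
        noise_int = rng.lognormal(cfg.noise_intensity_mu, cfg.intensity_sigma, n_noise)
        mzs.extend(noise_mz.tolist())
        intens.extend(noise_int.tolist())
    return Spectrum(
        spectrum_id=spectrum_id,
        precursor_mz=precursor,
        precursor_charge=z,
        mz=np.array(mzs),
        intensity=np.array(intens),
        replicate_id=replicate,
        fraction_id=fraction,
        strain_id=strain,
    )


def _noise_spectrum(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    spectrum_id: str,
    strain: str,
    replicate: str,
    fraction: str,
) -> Spectrum:
    n = cfg.n_noise_peaks
    return Spectrum(
        spectrum_id=spectrum_id,
        precursor_mz=float(rng.uniform(*cfg.ms1_range)),
        precursor_charge=int(rng.choice([2, 3])),
        mz=rng.uniform(cfg.noise_mz_range[0], cfg.noise_mz_range[1], n),
        intensity=rng.lognormal(cfg.noise_intensity_mu, cfg.intensity_sigma, n),
        replicate_id=replicate,
        fraction_id=fraction,
        strain_id=strain,
    )


def generate_dataset(
    cfg: GeneratorConfig,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, str], dict[tuple[str, str, str], list[Spectrum]], GroundTruth]:
    """Full synthetic study: proteome, per-(strain, replicate, fraction)
    spectra, and ground truth.

    When ``out_dir`` is given, writes ``proteome.fasta``, one MGF per
    (strain, replicate, fraction), and truth TSVs.  Deterministic under
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    proteins, sites = generate_proteome(cfg, rng)
    _assign_glycans(cfg, sites, rng)
    forms = _build_planted_forms(cfg, proteins, sites, rng)

    secreted_fracs = (["Mem", "SN", "Cyt"], [0.5, 0.3, 0.2])
    cytosol_fracs = (["Cyt", "Mem", "SN"], [0.7, 0.2, 0.1])
    n_secreted = round(cfg.n_proteins * cfg.fraction_secreted)

    buckets: dict[tuple[str, str, str], list[Spectrum]] = defaultdict(list)
    spectrum_truth: dict[str, str | None] = {}
    counter = 0
    for pf in forms:
        n_spec = min(cfg.max_spectra_per_form, int(rng.geometric(0.5)))
        pf.n_spectra = n_spec
        protein_index = int(pf.form.span.protein_id[1:])
        frac_names, frac_probs = (
            secreted_fracs if protein_index < n_secreted else cytosol_fracs
        )
        for _ in range(n_spec):
            replicate = f"R{int(rng.integers(cfg.n_replicates)) + 1}"
            fraction = (
                frac_names[int(rng.choice(len(frac_names), p=frac_probs))]
                if frac_names
                else ""
            )
            fraction = fraction if fraction in cfg.fractions else cfg.fractions[0]
            counter += 1
            sid = f"{pf.strain}.{replicate}.{fraction}.{counter:05d}"
            # per-spectrum child stream: peak-level randomness must not
            # perturb the study layout (spectra counts, replicates)
            spec_rng = np.random.default_rng((cfg.seed, 9173, counter))
            spectrum = simulate_spectrum(
                pf.form, cfg, spec_rng, sid, pf.strain, replicate, fraction
            )
            buckets[(pf.strain, replicate, fraction)].append(spectrum)
            spectrum_truth[sid] = pf.form.key()
            pf.replicate_ids.add(replicate)

    n_planted = counter
    n_noise = int(round(cfg.noise_spectrum_rate * n_planted))
    for _ in range(n_noise):
        strain = sorted(cfg.strains)[int(rng.integers(len(cfg.strains)))]
        replicate = f"R{int(rng.integers(cfg.n_replicates)) + 1}"
        fraction = cfg.fractions[int(rng.integers(len(cfg.fractions)))]
        counter += 1
        sid = f"{strain}.{replicate}.{fraction}.{counter:05d}"
        spec_rng = np.random.default_rng((cfg.seed, 9173, counter))
        buckets[(strain, replicate, fraction)].append(
            _noise_spectrum(cfg, spec_rng, sid, strain, replicate, fraction)
        )
        spectrum_truth[sid] = None

    truth = GroundTruth(spectrum_truth, forms, sites)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(proteins, out / "proteome.fasta")
        for strain in sorted(cfg.strains):
            for r in range(1, cfg.n_replicates + 1):
                for fraction in cfg.fractions:
                    key = (strain, f"R{r}", fraction)
                    write_mgf(
                        buckets.get(key, []), out / f"{strain}_R{r}_{fraction}.mgf"
                    )
        _write_truth_tables(out, truth)
    return proteins, dict(buckets), truth


def _write_truth_tables(out: Path, truth: GroundTruth) -> None:
    lines = ["spectrum_id\tpeptidoform"]
    for sid in sorted(truth.spectrum_truth):
        key = truth.spectrum_truth[sid]
        lines.append(f"{sid}\t{key if key is not None else 'noise'}")
    (out / "truth_spectra.tsv").write_text("\n".join(lines) + "\n")

    lines = [
        "strain\tpeptidoform\tprotein\tsites\tpathway\tn_spectra\t"
        "n_replicates\teligible\texpected_rejected_reason"
    ]
    for pf in truth.planted_forms:
        reason = ""
        if pf.form.is_glyco and not pf.eligible:
            if pf.n_spectra < 2:
                reason = "expected-rejected (spectral count rule)"
            elif len(pf.replicate_ids) < 2:
                reason = "expected-rejected (replicate rule)"
        lines.append(
            "\t".join(
                [
                    pf.strain,
                    pf.form.key(),
                    pf.form.span.protein_id,
                    ",".join(map(str, pf.site_positions)),
                    pf.pathway or "",
                    str(pf.n_spectra),
                    str(len(pf.replicate_ids)),
                    str(pf.form.is_glyco and pf.eligible),
                    reason,
                ]
            )
        )
    (out / "truth_glycopeptidoforms.tsv").write_text("\n".join(lines) + "\n")

    lines = ["protein\tposition\tresidue\tcanonical\tglycosylated\tpathway\tglycan"]
    for s in truth.sites:
        lines.append(
            f"{s.protein_id}\t{s.position}\t{s.residue}\t{s.canonical}\t"
            f"{s.glycosylated}\t{s.pathway or ''}\t{s.glycan or ''}"
        )
    (out / "truth_sites.tsv").write_text("\n".join(lines) + "\n")
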