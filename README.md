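# glycopipe

Glycan-aware peptide identification for prokaryotic N-glycoproteomes:
in-silico digestion, per-glycan database searching, combined-PEP
scoring, peptidoform/protein target-decoy FDR, glycan fragment-ion
(Y/B) validation, sequon classification, and strain-level comparison —
plus a ground-truthed synthetic MS2 study generator so every stage is
testable without instrument data.

## The problem

In halophilic archaea such as *Haloferax volcanii*, two independent
N-glycosylation pathways operate side by side: an AglB-dependent
pentasaccharide series (Hex, Hex-HexA, Hex-HexA₂, Hex-HexA₂-MeHexA,
Hex₂-HexA₂-MeHexA) and an Agl15-dependent sulfated tetrasaccharide
series (SO₃Hex, SO₃Hex-Hex, SO₃Hex-Hex₂, SO₃Hex-Hex₂-dHex), alongside
an O-linked dihexose on S/T.  Mapping which asparagines carry which
glycans from shotgun MS2 data requires searching each glycan
composition as a separate variable modification and then filtering the
union of searches stringently enough that the enlarged search space
does not flood the results with false identifications.  Deletion
strains lacking one pathway (ΔaglB, Δagl15) act as biological negative
controls: no glycopeptide of the deleted pathway should survive the
filters.

`glycopipe` is aimed at method developers and analysts who want this
filtering machinery — PEP estimation from target-decoy competition,
combined PEPs across engines and searches, peptidoform-level FDR,
glyco-ion evidence rules, replicate requirements — as a tested,
self-contained library with a built-in benchmark.

## The statistics at the core

A PSM's posterior error probability is estimated from the local decoy
density in the score ranking, PEP = min(1, 2·D_w/W) over a rank window
with isotonic smoothing; scores from several engines are combined by
S = Σ_e −log₁₀(PEP_e) and re-ranked.  Identifications then pass an
ordered cascade: combined PEP ≤ 1% → one PSM per spectrum (best PEP;
isobarically indistinguishable spectra are dropped) → peptidoform
q-value ≤ 1% (FDR = #decoys/#targets, q = running minimum) → protein
q-value ≤ 0.5% → ≥ 2 spectra per peptidoform → for glycopeptidoforms,
≥ 2 glyco Y ions and ≥ 1 B/oxonium ion in a single spectrum and
presence in ≥ 2 replicates.  See `docs/methods.md` for the full model,
parameter table and design rationale.

## Worked example

Simulate a three-strain study (wild type, Δagl15, ΔaglB; 2 replicates ×
3 fractions) and run the pipeline on it:

```bash
glycopipe simulate --seed 7 --out data
glycopipe run --fasta data/proteome.fasta --mgf-dir data --out results
```

which prints:

```
wrote 18 MGF files (569 spectra, 241 planted peptidoforms) to data
[WT] pep_filter=213, sanitized=168, peptidoform_fdr=88, protein_fdr=88, min_spectra=44, glyco_rules=13, accepted=41
[dagl15] pep_filter=256, sanitized=196, peptidoform_fdr=84, protein_fdr=84, min_spectra=51, glyco_rules=8, accepted=48
[daglB] pep_filter=120, sanitized=119, peptidoform_fdr=66, protein_fdr=66, min_spectra=26, glyco_rules=1, accepted=25
accepted: 15 glycopeptidoforms, 15 glycosites, 13 glycoproteins
```

Each strain line is the filter cascade's survivor count per stage: PSMs
passing the 1% combined-PEP cut, spectra surviving sanitization,
peptidoforms under the 1% peptidoform and 0.5% protein FDR, those with
≥ 2 spectra, glycopeptidoforms passing the Y/B-ion and ≥ 2-replicate
rules, and the total accepted peptidoforms.  Note the ΔaglB strain
retains only a single glycopeptidoform (an Agl15-pathway one) — the
deleted pathway's glycans are planted nowhere in that strain, and none
are falsely recovered.  `results/glycosites.tsv` maps each accepted
glycopeptidoform onto protein coordinates:

```
protein_id  position  mature_position  residue  sequon_class  pathways  glycans                 psm_count  replicates  datasets
P000        37        37               N        canonical     AglB      Hex(2)HexA(2)MeHexA(1)  5          R1,R2       WT
P001        555       555              N        canonical     AglB      Hex(2)HexA(2)MeHexA(1)  3          R1,R2       WT
P009        207       207              N        canonical     Agl15     SO3Hex(1)Hex(2)dHex(1)  2          R1,R2       WT
```

`data/truth_*.tsv` hold the planted ground truth (per-spectrum
peptidoform, per-form eligibility under the spectra/replicate rules,
per-site glycan and pathway), so recall and the realized
false-discovery proportion of any run can be measured exactly.
`glycopipe report --psms results/psms.tsv --fasta data/proteome.fasta
--out report` re-applies the cascade to a saved PSM table, e.g. one
produced by an external search engine through the TSV adapter.

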