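# Methods

`glycopipe` implements a glycan-aware peptide identification workflow
for prokaryotic N-glycoproteomes of the kind found in halophilic
archaea, where two independent N-glycosylation pathways (an
AglB-dependent pentasaccharide series and an Agl15-dependent sulfated
tetrasaccharide series) plus an O-linked dihexose coexist, and where
deletion strains lacking one pathway serve as biological negative
controls.  This note records the model, the parameters that matter,
the numerical choices, and what the synthetic benchmark does and does
not demonstrate.

## Search model

Proteins are digested fully specifically (trypsin: after K/R unless
followed by P; GluC: after E, with an E+D variant selectable) with a
configurable number of missed cleavages (default 2, matching common
trypsin settings; 3 is typical for GluC).  Candidate peptidoforms carry
carbamidomethyl-C as a fixed modification, up to one variable
modification (oxidation-M or N-terminal acetyl by default), and — in a
glycopeptide search — one glycan composition placed on up to two
eligible residues.  Because widely used engines cannot search two
different modifications of the same residue simultaneously, each glycan
composition is searched separately and results are merged afterwards;
this also means a peptide cannot be assigned one glycan of each pathway
in a single search.

Glycans are modeled as linear chains written peptide-proximal first.
Residue chemistry is derived from the dehydrated monosaccharides
(Hex C6H10O5, HexA C6H8O6, MeHexA C7H10O6, dHex C6H10O4, SO3Hex
C6H10O8S) and a glycan's mass is the residue sum — glycosidic
attachment is a condensation, so no water term is added.  One published
composition row (Hex(1)HexA(1)) prints the lone HexA residue formula
instead of the disaccharide sum; the residue-sum rule is used
throughout and that row is surfaced as a validation warning rather than
silently adopted.

Theoretical fragments comprise backbone b/y ions (charge 1 by default)
with site modifications riding on fragments that contain the modified
residue; since N/O-glycans are labile under HCD, a glycan-less variant
of every glycan-carrying backbone ion is also generated.  Glyco Y ions
(peptide + proximal sugars, Y0 = bare peptide) and B/oxonium ions
(terminal sugars) come from interglycosidic cleavage and are matched at
charges 1-2.  B ions follow the oxocarbenium convention (residue mass +
proton); theoretical B ions below the acquisition window's fixed first
mass (130 m/z) are excluded from evidence requirements.

Peak matching assigns each theoretical ion to the nearest peak within
an inclusive ppm window (backbone 10 ppm, glyco 20 ppm by default),
breaking exact-distance ties toward the higher-intensity peak.  One
peak may satisfy several ion labels.

## Scoring and error control

The built-in engine scores a candidate as

    score = n_matched_peaks x ln(1 + matched_intensity / total_intensity)

where `n_matched_peaks` counts *distinct* matched peaks.  Counting
peaks rather than ion labels is deliberate: with the labile-glycan
convention a single peak can satisfy both a plain and a glycan-less
label, and label counting would let isobaric glycan placements inflate
their score by label multiplicity.  An external-engine adapter (TSV
contract: spectrum, peptidoform string, score, optional PEP, decoy
flag) lets real search-engine output replace the naive engine without
code changes.

Decoys are shuffled peptides with the C-terminal residue pinned
(preserving protease specificity); in the pipeline they are generated
as a decoy database at the peptide level and enumerated into
peptidoforms exactly like targets, so modification eligibility is
recomputed on the shuffled sequence.

Posterior error probabilities come from the local decoy density in the
score ranking: PEP = min(1, 2 D_w / W) over a centered rank window,
followed by pool-adjacent-violators isotonic smoothing so PEPs never
decrease with worsening rank.  The factor 2 reflects the concatenated
target-decoy symmetry assumption.  The window adapts to the list size
(about a tenth of the list, floor 31, cap 101): a fixed wide window has
granularity 2/W, which at W=101 makes a 1% PEP cut equivalent to
demanding a decoy-free window, and lets a handful of bottom-ranked
decoys bleed error mass far up a sharp score cliff on small datasets.
Scores from the built-in engine are comparable across per-glycan
searches, so its PEP is estimated on the pooled ranking; PEPs from
different engines are combined by summing -log10(PEP) (floor 1e-6)
within groups of PSMs sharing the same engine set and re-estimating the
PEP on the re-ranked group, with singleton groups keeping their own
PEP.

Sanitization keeps one PSM per spectrum: lowest combined PEP, then
highest raw score.  Remaining exact ties are isobaric peptidoforms the
spectrum cannot distinguish (typically glycan placements whose
site-determining fragments went undetected).  Placements of the *same*
glycan set on the same peptide are resolved by a biological prior —
prefer the placement at a canonical N-X-S/T sequon — mirroring standard
practice in which noncanonical sites only surface when the sequon
requirement is deliberately lifted.  Ties across different glycan
compositions, or against a decoy, or unresolved by the prior, cause the
spectrum to be discarded as ambiguous; engine-level ties inside one
search are carried on the PSM (an `ambiguous` flag) so the spectrum is
discarded even when its competitors sit in different searches.  Without
this policy, alphabetical tie-breaking turned systematic isobaric
coincidences (e.g. Hex(2) on S/T vs 2x Hex(1) on two N residues, which
share every non-discriminating peak *and* most of the Y ladder) into
accepted false identifications.

The filter cascade then applies, in order: combined PEP <= 1%;
sanitization; peptidoform q-value <= 1% (target-decoy FDR = D/T with a
running-minimum q-value, each peptidoform = peptide + exact
modification set); protein q-value <= 0.5% (each protein represented by
its best peptidoform); >= 2 spectra per peptidoform; and for
glycopeptidoforms additionally >= 2 distinct glyco Y rungs plus >= 1
B/oxonium ion co-occurring in at least one spectrum (the B requirement
can be waived for data without the low-m/z range) and presence in >= 2
replicates.  Survivor counts are reported per stage.

## Synthetic benchmark

The generator emulates the structure of a fractionated three-strain
study: 50 random proteins (120-600 residues, 60% secreted), canonical
N-X-S/T sequons planted in secreted proteins at 0.7 per 100 residues
with a 10% noncanonical quota, half of the sites glycosylated, pathway
mix 85% AglB / 10% Agl15 / 5% O-linked (matching the observed dominance
of AglB-dependent glycans), full-length glycans drawn with probability
0.6 and pathway intermediates otherwise, and two sites additionally
observed with a glycan of the other pathway to exercise pathway-union
reporting.  Three strains (wild type and one deletion per N-pathway,
each lacking that pathway's glycans entirely), two replicates, three
fractions (membrane/cytosol/supernatant), and ~80 background
non-glycosylated peptides per strain.  Each planted peptidoform
receives 1-6 spectra (geometric, mean 2) spread over replicates and
fractions, so the >= 2 spectra and >= 2 replicates rules are genuinely
exercised; forms that cannot satisfy them are flagged
"expected-rejected" in the truth tables.  Accidental N-X-S/T motifs in
secreted proteins are disrupted before planting so sequon density is an
exact control.

Spectra are Bernoulli-thinned theoretical peak sets (backbone detection
0.7, glyco 0.8) with 3 ppm Gaussian m/z jitter, log-normal intensities
(ln-mean 10 for signal, 8.5 for noise, sigma 1), 30 uniform noise peaks
per spectrum in 130-2000 m/z, a 15% rate of noise-only spectra,
precursor charges 2-4 inside a 400-2000 m/z survey range, and an MS2
window of 130-2000 m/z.  Peak-level randomness uses a per-spectrum
child RNG stream so that changing detection parameters does not perturb
the study layout — recall comparisons across settings are paired.
Identical seed and configuration give byte-identical output files.

What the benchmark does *not* emulate: isotope envelopes, retention
time and LC effects, chimeric spectra, intensity structure beyond
log-normal draws, charge-dependent fragmentation, and real engine score
distributions.  Passing tests therefore demonstrate the correctness of
the statistical machinery and the end-to-end bookkeeping under the
stated noise model, not instrument-level performance on real data.

## Measured behavior and problem sizes

At the default settings, one study is ~600 spectra across 18 files, and
the test suite and acceptance script pool 20 seeded runs (a few minutes
in total).  Pooled over 20 runs the pipeline recovers ~87% of
replicate-eligible planted glycopeptidoforms with a realized glyco
false-discovery proportion of 0-1% at the nominal 1% FDR, and the
AglB-knockout strain yields zero AglB-pathway glycopeptidoforms in all
runs.  Recall rises steeply with the per-ion detection probability and
saturates near 0.9: above ~0.65 detection, residual losses are
dominated by short glycopeptides whose PSMs sit near the decoy score
region and by spectra discarded as isobarically ambiguous, so the
recall-vs-detection curve is monotone from low to mid/high but flat (and
occasionally non-monotone by a form or two) between the two highest
settings.

## Known limitations

Site localization rests on glycan-carrying backbone fragments only; a
dedicated localization score (and per-site confidence) is not
implemented — indistinguishable placements are resolved by the sequon
prior or discarded.  Peptides shared between proteins are assigned to
the lexicographically first protein rather than to explicit protein
groups.  Protein-level error control uses the best peptidoform per
protein without razor-peptide logic.  The PEP estimator is
rank-windowed and granular; on very small PSM sets its 1% cut behaves
like a "no nearby decoys" rule rather than a smooth posterior.
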