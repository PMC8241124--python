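"""Spectrum I/O, fragment matching, the naive engine and the glyco
fragment-ion evidence rule."""

import numpy as np
import pytest

from glycopipe.chem import PROTON_MASS, peptide_mass, mz_from_mass
from glycopipe.digestion import PeptideSpan, Peptidoform, make_decoy
from glycopipe.glycans import default_glycan_table, glycan_mass
from glycopipe.spectra import (
    PSM,
    FragmentMatchResult,
    Spectrum,
    glyco_ion_evidence,
    match_peaks,
    naive_engine_score,
    read_mgf,
    theoretical_backbone_ions,
    theoretical_glyco_ions,
    write_mgf,
)
from glycopipe.synthetic_data import GeneratorConfig, simulate_spectrum

GLYCANS = {g.name: g for g in default_glycan_table()}


def make_spectrum(mz, intensity=None, **kwargs):
    mz = np.asarray(mz, dtype=float)
    if intensity is None:
        intensity = np.ones_like(mz)
    defaults = dict(spectrum_id="s1", precursor_mz=500.0, precursor_charge=2)
    defaults.update(kwargs)
    return Spectrum(mz=mz, intensity=np.asarray(intensity, float), **defaults)


class TestMGF:
    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.mgf"
        path.write_text("")
        assert read_mgf(path) == []

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        spectra = [
            make_spectrum(
                np.sort(rng.uniform(130, 2000, 25)),
                rng.lognormal(8, 1, 25),
                spectrum_id=f"spec{i}",
                precursor_mz=float(rng.uniform(400, 2000)),
                precursor_charge=int(rng.integers(2, 5)),
                strain_id="WT",
                replicate_id="R1",
                fraction_id="Mem",
            )
            for i in range(5)
        ]
        path = tmp_path / "spectra.mgf"
        write_mgf(spectra, path)
        back = read_mgf(path)
        assert len(back) == 5
        for a, b in zip(spectra, back):
            assert b.spectrum_id == a.spectrum_id
            assert b.precursor_charge == a.precursor_charge
            assert b.strain_id == "WT" and b.replicate_id == "R1"
            assert b.precursor_mz == pytest.approx(a.precursor_mz, abs=1e-4)
            assert b.mz == pytest.approx(a.mz, abs=1e-4)

    def test_charge_one_parsed_but_not_searchable(self, tmp_path):
        s = make_spectrum([200.0, 300.0], precursor_charge=1)
        path = tmp_path / "z1.mgf"
        write_mgf([s], path)
        (back,) = read_mgf(path)
        assert back.precursor_charge == 1
        assert not back.searchable

    def test_charge_range(self):
        assert make_spectrum([100.0], precursor_charge=2).searchable
        assert make_spectrum([100.0], precursor_charge=6).searchable
        assert not make_spectrum([100.0], precursor_charge=7).searchable


class TestBackboneIons:
    def test_dipeptide_has_b1_y1_only(self):
        form = Peptidoform(PeptideSpan("p", 1, 2, "GG"))
        labels = {lab for lab, _ in theoretical_backbone_ions(form)}
        assert labels == {"b1+1", "y1+1"}

    def test_b1_of_AG(self):
        form = Peptidoform(PeptideSpan("p", 1, 2, "AG"))
        ions = dict(theoretical_backbone_ions(form))
        assert ions["b1+1"] == pytest.approx(71.03711 + PROTON_MASS, abs=1e-3)

    def test_bk_plus_ynk_equals_peptide_mass(self):
        seq = "SAMPLEPEPTIDEK"
        form = Peptidoform(PeptideSpan("p", 1, len(seq), seq))
        ions = dict(theoretical_backbone_ions(form))
        n = len(seq)
        m = form.neutral_mass
        for k in range(1, n):
            b_neutral = ions[f"b{k}+1"] - PROTON_MASS
            y_neutral = ions[f"y{n - k}+1"] - PROTON_MASS
            assert b_neutral + y_neutral == pytest.approx(m, abs=1e-6)

    def test_glycopeptide_emits_glycanless_variants(self):
        hex1 = GLYCANS["Hex(1)"]
        form = Peptidoform(PeptideSpan("p", 1, 4, "ANSK"), glyco_mods=((2, hex1),))
        ions = dict(theoretical_backbone_ions(form))
        assert ions["b2+1"] - ions["b2-glycan+1"] == pytest.approx(
            glycan_mass(hex1), abs=1e-6
        )

    def test_rejects_single_residue(self):
        with pytest.raises(ValueError):
            theoretical_backbone_ions(Peptidoform(PeptideSpan("p", 1, 1, "G")))


class TestGlycoIons:
    def test_y0_is_bare_peptidoform(self):
        hex1 = GLYCANS["Hex(1)"]
        form = Peptidoform(PeptideSpan("p", 1, 4, "ANSK"), glyco_mods=((2, hex1),))
        ions = dict(theoretical_glyco_ions(form, charges=(1,)))
        bare = form.neutral_mass - glycan_mass(hex1)
        assert ions["Y0@2+1"] == pytest.approx(mz_from_mass(bare, 1), abs=1e-6)
        assert ions["B1+1"] == pytest.approx(
            mz_from_mass(glycan_mass(hex1), 1), abs=1e-6
        )

    def test_oxonium_floor_suppresses_low_mz_B_ions(self):
        hex1 = GLYCANS["Hex(1)"]
        form = Peptidoform(PeptideSpan("p", 1, 4, "ANSK"), glyco_mods=((2, hex1),))
        ions = theoretical_glyco_ions(form, charges=(1,), min_mz=200.0)
        assert not any(lab.startswith("B") for lab, _ in ions)

    def test_nonglyco_form_has_no_glyco_ions(self):
        assert theoretical_glyco_ions(Peptidoform(PeptideSpan("p", 1, 2, "AK"))) == []


class TestMatchPeaks:
    def test_exact_peaks_all_match(self):
        theo = [("b1+1", 200.0), ("y1+1", 500.0), ("b2+1", 900.0)]
        s = make_spectrum([mz for _, mz in theo])
        res = match_peaks(s, theo, 20.0)
        assert res.n_backbone == 3
        assert res.ppm_errors == pytest.approx([0.0, 0.0, 0.0], abs=1e-9)

    def test_shifted_beyond_tolerance_no_match(self):
        theo = [("b1+1", 200.0), ("y1+1", 500.0)]
        s = make_spectrum([mz * (1 + 25e-6) for _, mz in theo])
        assert match_peaks(s, theo, 20.0).n_backbone == 0

    def test_boundary_is_inclusive(self):
        s = make_spectrum([500.0 * (1 + 20e-6)])
        res = match_peaks(s, [("y1+1", 500.0)], 20.0)
        assert res.n_backbone == 1
        assert res.ppm_errors[0] == pytest.approx(20.0, abs=1e-6)

    def test_tolerance_monotone(self):
        rng = np.random.default_rng(1)
        theo = [(f"b{i}+1", float(m)) for i, m in enumerate(rng.uniform(150, 1800, 30))]
        peaks = np.sort(rng.uniform(150, 1800, 120))
        s = make_spectrum(peaks)
        for t1, t2 in [(5.0, 10.0), (10.0, 20.0), (20.0, 50.0)]:
            m1 = set(match_peaks(s, theo, t1).matched_labels)
            m2 = set(match_peaks(s, theo, t2).matched_labels)
            assert m1 <= m2

    def test_tie_broken_toward_higher_intensity(self):
        s = make_spectrum([500.0 - 0.001, 500.0 + 0.001], [1.0, 10.0])
        res = match_peaks(s, [("y1+1", 500.0)], 20.0)
        assert res.matched_peak_indices == [1]


class TestNaiveEngine:
    def test_zero_matches_scores_zero(self):
        form = Peptidoform(PeptideSpan("p", 1, 5, "GAVLK"))
        s = make_spectrum([1900.0, 1950.0])
        assert naive_engine_score(s, form) == 0.0

    def test_deterministic(self):
        cfg = GeneratorConfig(seed=0)
        form = Peptidoform(PeptideSpan("p", 1, 8, "SAMPLEKK"))
        s = simulate_spectrum(form, cfg, np.random.default_rng(3))
        assert naive_engine_score(s, form) == naive_engine_score(s, form)

    def test_invariant_to_intensity_scaling_and_peak_order(self):
        form = Peptidoform(PeptideSpan("p", 1, 8, "SAMPLEKK"))
        cfg = GeneratorConfig(seed=0)
        s = simulate_spectrum(form, cfg, np.random.default_rng(4))
        scaled = make_spectrum(
            s.mz, s.intensity * 7.5,
            precursor_mz=s.precursor_mz, precursor_charge=s.precursor_charge,
        )
        order = np.random.default_rng(0).permutation(s.mz.size)
        shuffled = make_spectrum(
            s.mz[order], s.intensity[order],
            precursor_mz=s.precursor_mz, precursor_charge=s.precursor_charge,
        )
        base = naive_engine_score(s, form)
        assert naive_engine_score(scaled, form) == pytest.approx(base, rel=1e-12)
        assert naive_engine_score(shuffled, form) == pytest.approx(base, rel=1e-12)

    def test_planted_spectrum_outscores_random_decoy(self):
        """Over 100 simulated spectra, the true peptidoform beats a
        shuffled decoy of equal length and composition >= 95% of the
        time."""
        rng = np.random.default_rng(42)
        cfg = GeneratorConfig(seed=0)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        wins = total = 0
        while total < 100:
            seq = "".join(rng.choice(list(aa), 11)) + "K"
            form = Peptidoform(PeptideSpan("p", 1, 12, seq))
            decoy = make_decoy(form, seed=int(rng.integers(1, 1000)))
            if decoy.sequence == form.sequence:
                continue
            s = simulate_spectrum(form, cfg, rng)
            total += 1
            if naive_engine_score(s, form) > naive_engine_score(s, decoy):
                wins += 1
        assert wins / total >= 0.95


class TestGlycoEvidence:
    def _psm(self, labels):
        form = Peptidoform(
            PeptideSpan("p", 1, 4, "ANSK"), glyco_mods=((2, GLYCANS["Hex(1)"]),)
        )
        ev = FragmentMatchResult(matched_labels=list(labels))
        return PSM(spectrum_id="s", peptidoform=form, glyco_evidence=ev)

    def test_y0_y1_b1_in_one_spectrum_passes(self):
        assert glyco_ion_evidence([self._psm(["Y0@2+1", "Y1@2+1", "B1+1"])])

    def test_y_only_passes_when_oxonium_not_required(self):
        psm = self._psm(["Y0@2+1", "Y1@2+2"])
        assert not glyco_ion_evidence([psm], require_oxonium=True)
        assert glyco_ion_evidence([psm], require_oxonium=False)

    def test_criteria_must_cooccur_in_one_spectrum(self):
        split = [self._psm(["Y0@2+1", "B1+1"]), self._psm(["Y1@2+1", "Y2@2+1"])]
        assert not glyco_ion_evidence(split, require_oxonium=True)

    def test_charge_states_of_one_rung_count_once(self):
        psm = self._psm(["Y0@2+1", "Y0@2+2", "B1+1"])
        assert not glyco_ion_evidence([psm])  # only one distinct Y rung

    def test_empty_psm_list_is_an_error(self):
        with pytest.raises(ValueError):
            glyco_ion_evidence([])
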