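"""PEP estimation, combined PEP, sanitization, FDR and the filter
cascade."""

import numpy as np
import pytest

from glycopipe.digestion import PeptideSpan, Peptidoform
from glycopipe.glycans import default_glycan_table
from glycopipe.spectra import PSM, FragmentMatchResult
from glycopipe.stats import (
    FilterConfig,
    apply_filter_cascade,
    combine_peps,
    combined_score,
    estimate_pep,
    fdr_qvalues,
    resolve_candidate_tie,
    sanitize,
)

GLYCANS = {g.name: g for g in default_glycan_table()}
HEX1 = GLYCANS["Hex(1)"]


def form(seq, glyco=(), decoy=False, protein="P", start=1):
    span = PeptideSpan(protein, start, start + len(seq) - 1, seq)
    return Peptidoform(span, glyco_mods=tuple(glyco), is_decoy=decoy)


def psm(spectrum_id, peptidoform, pep=1.0, score=0.0, replicate="", evidence=None):
    return PSM(
        spectrum_id=spectrum_id,
        peptidoform=peptidoform,
        engine_scores={"naive": score} if score else {},
        combined_pep=pep,
        replicate_id=replicate,
        glyco_evidence=evidence,
    )


GOOD_EVIDENCE = FragmentMatchResult(matched_labels=["Y0@2+1", "Y1@2+1", "B1+1"])
WEAK_EVIDENCE = FragmentMatchResult(matched_labels=["Y0@2+1"])


class TestEstimatePep:
    def test_all_targets_gives_zero(self):
        peps = estimate_pep([False] * 300, window=101)
        assert np.all(peps == 0.0)

    def test_all_decoys_capped_at_one(self):
        peps = estimate_pep([True] * 300, window=101)
        assert np.all(peps == 1.0)

    def test_alternating_list_approaches_one(self):
        flags = [i % 2 == 1 for i in range(400)]
        peps = estimate_pep(flags, window=101)
        # local decoy fraction 1/2, doubled and capped
        assert np.all(peps >= 0.98)

    def test_short_list_single_window_fallback(self):
        peps = estimate_pep([False, True, False, False], window=101)
        assert peps == pytest.approx([0.5] * 4)

    def test_output_is_non_decreasing_down_the_ranking(self):
        rng = np.random.default_rng(0)
        flags = rng.random(500) < np.linspace(0, 0.6, 500)
        peps = estimate_pep(list(flags), window=101)
        assert np.all(np.diff(peps) >= -1e-12)

    def test_rejects_even_or_tiny_window(self):
        with pytest.raises(ValueError):
            estimate_pep([False] * 10, window=100)
        with pytest.raises(ValueError):
            estimate_pep([False] * 10, window=1)


class TestCombinePeps:
    def test_single_psm_keeps_its_own_pep(self):
        p = psm("s1", form("LLAK"))
        p.engine_peps = {"engine_a": 0.2}
        combine_peps([p])
        assert p.combined_pep == pytest.approx(0.2)

    def test_multi_engine_combined_score_ranks_higher(self):
        three = combined_score({"a": 0.01, "b": 0.01, "c": 0.01})
        one = combined_score({"a": 0.01})
        assert three > one

    def test_group_reestimation_matches_hand_computed_window(self):
        """20 PSMs seen by two engines, 2 decoys: below the window size
        the estimator collapses to a single window, so every combined
        PEP equals 2 x 2/20."""
        psms = []
        for i in range(20):
            p = psm(f"s{i}", form("LLAK" if i < 18 else "KALL", decoy=i >= 18))
            p.engine_peps = {"a": 0.001 * (i + 1), "b": 0.002 * (i + 1)}
            psms.append(p)
        combine_peps(psms)
        for p in psms:
            assert p.combined_pep == pytest.approx(0.2)

    def test_empty_engine_map_is_an_error(self):
        with pytest.raises(ValueError):
            combine_peps([psm("s1", form("LLAK"))])


class TestSanitize:
    def test_single_psm_unchanged(self):
        p = psm("s1", form("LLAK"), pep=0.5)
        assert sanitize([p]) == [p]

    def test_best_pep_wins(self):
        worse = psm("s1", form("GGGR"), pep=0.01)
        better = psm("s1", form("LLAK"), pep=0.001)
        assert sanitize([worse, better]) == [better]

    def test_pep_tie_broken_by_raw_score(self):
        low = psm("s1", form("GGGR"), pep=0.01, score=2.0)
        high = psm("s1", form("LLAK"), pep=0.01, score=9.0)
        assert sanitize([low, high]) == [high]

    def test_indistinguishable_isobaric_glycans_drop_the_spectrum(self):
        a = psm("s1", form("ANSTK", glyco=((2, HEX1),)), pep=0.01, score=5.0)
        b = psm("s1", form("ANSTK", glyco=((4, GLYCANS["Hex(2)"]),)), pep=0.01, score=5.0)
        assert sanitize([a, b]) == []

    def test_same_glycan_tie_resolved_by_sequon_prior(self):
        # N2 sits in an N-X-S sequon; N5 does not
        canonical = psm("s1", form("ANGSNK", glyco=((2, HEX1),)), pep=0.01, score=5.0)
        other = psm("s1", form("ANGSNK", glyco=((5, HEX1),)), pep=0.01, score=5.0)
        assert sanitize([other, canonical]) == [canonical]

    def test_engine_flagged_ambiguity_drops_the_spectrum(self):
        p = psm("s1", form("ANSTK", glyco=((2, HEX1),)), pep=0.001, score=5.0)
        p.ambiguous = True
        assert sanitize([p]) == []


class TestResolveCandidateTie:
    def test_identical_keys_resolve_trivially(self):
        f = form("LLAK")
        assert resolve_candidate_tie([f, f]) is f

    def test_different_glycan_sets_are_ambiguous(self):
        a = form("ANSTK", glyco=((2, HEX1),))
        b = form("ANSTK", glyco=((4, GLYCANS["Hex(2)"]),))
        assert resolve_candidate_tie([a, b]) is None

    def test_target_decoy_tie_is_ambiguous(self):
        assert resolve_candidate_tie([form("LLAK"), form("LALK", decoy=True)]) is None


class TestFdrQvalues:
    def test_hand_computed_example(self):
        # ranking T,T,D,T: FDRs 0,0,1/2,1/3 -> q-values 0,0,1/3,1/3
        q = fdr_qvalues([False, False, True, False])
        assert q == pytest.approx([0.0, 0.0, 1 / 3, 1 / 3])

    def test_all_targets(self):
        assert fdr_qvalues([False] * 5) == pytest.approx([0.0] * 5)

    def test_leading_decoys_capped_at_one(self):
        q = fdr_qvalues([True, True, False])
        assert q == pytest.approx([1.0, 1.0, 1.0])

    def test_no_targets_is_an_error(self):
        with pytest.raises(ValueError):
            fdr_qvalues([True, True])

    def test_monotone_down_the_ranking(self):
        rng = np.random.default_rng(1)
        flags = list(rng.random(200) < 0.2)
        flags[0] = False
        q = fdr_qvalues(flags)
        assert np.all(np.diff(q) >= -1e-12)


def toy_psm_table():
    """Twelve hand-constructed PSMs exercising every cascade stage.

    Peptidoform A (3 spectra incl. a sanitization win, 2 replicates)
    and glycopeptidoform G (2 spectra, 2 replicates, Y0+Y1+B1 in one
    spectrum) are accepted.  H fails the replicate rule, B the spectral
    count, E the PEP cut, M loses sanitization, D is the decoy driving
    the q-values.
    """
    form_A = form("LLAK", protein="PA")
    form_G = form("ANSTK", glyco=((2, HEX1),), protein="PG")
    form_H = form("GNVSR", glyco=((2, HEX1),), protein="PH")
    form_B = form("VVGGK", protein="PB")
    form_E = form("TTPLR", protein="PE")
    form_M = form("MMGGR", protein="PM")
    form_D = form("ALLK", decoy=True, protein="PD")
    return [
        psm("spec01", form_A, pep=0.001, score=9.0, replicate="R1"),
        psm("spec02", form_A, pep=0.002, score=8.0, replicate="R2"),
        psm("spec03", form_G, pep=0.001, score=9.0, replicate="R1", evidence=GOOD_EVIDENCE),
        psm("spec04", form_G, pep=0.004, score=6.0, replicate="R2", evidence=WEAK_EVIDENCE),
        psm("spec05", form_H, pep=0.002, score=8.0, replicate="R1", evidence=GOOD_EVIDENCE),
        psm("spec06", form_H, pep=0.003, score=7.0, replicate="R1", evidence=GOOD_EVIDENCE),
        psm("spec07", form_B, pep=0.005, score=5.0, replicate="R1"),
        psm("spec08", form_E, pep=0.05, score=2.0, replicate="R1"),
        psm("spec09", form_E, pep=0.02, score=2.5, replicate="R2"),
        psm("spec10", form_A, pep=0.001, score=9.0, replicate="R1"),
        psm("spec10", form_M, pep=0.008, score=4.0, replicate="R1"),
        psm("spec11", form_D, pep=0.009, score=3.0, replicate="R1"),
    ]


class TestFilterCascade:
    def test_empty_input(self):
        result = apply_filter_cascade([], FilterConfig())
        assert result.accepted_peptidoforms == []
        assert all(v == 0 for v in result.stage_counts.values())

    def test_hand_enumerated_toy_table(self):
        result = apply_filter_cascade(toy_psm_table(), FilterConfig())
        assert result.stage_counts == {
            "pep_filter": 10,   # E's two PSMs exceed PEP 1%
            "sanitized": 9,     # spec10 keeps A (PEP 0.001) over M
            "peptidoform_fdr": 4,  # A,G,H,B pass; decoy D at q=1/4 out
            "protein_fdr": 4,
            "min_spectra": 3,   # B has a single spectrum
            "glyco_rules": 1,   # H seen in one replicate only
            "accepted": 2,      # A and G
        }
        assert {g.key for g in result.accepted_glyco} == {"ANSTK[Hex(1)@2]"}
        assert {g.key for g in result.accepted_peptidoforms} == {
            "LLAK",
            "ANSTK[Hex(1)@2]",
        }

    def test_relaxing_min_spectra_accepts_superset(self):
        table = toy_psm_table()
        strict = apply_filter_cascade(table, FilterConfig(min_spectra_per_peptidoform=2))
        loose = apply_filter_cascade(table, FilterConfig(min_spectra_per_peptidoform=1))
        strict_keys = {g.key for g in strict.accepted_peptidoforms}
        loose_keys = {g.key for g in loose.accepted_peptidoforms}
        assert strict_keys <= loose_keys
        assert "VVGGK" in loose_keys - strict_keys

    @pytest.mark.parametrize(
        "tight, loose",
        [
            (FilterConfig(max_combined_pep=0.001), FilterConfig(max_combined_pep=0.01)),
            (FilterConfig(min_replicates=2), FilterConfig(min_replicates=1)),
            (FilterConfig(max_peptidoform_fdr=0.001), FilterConfig(max_peptidoform_fdr=0.5)),
        ],
    )
    def test_tightening_any_threshold_never_grows_accepted_set(self, tight, loose):
        table = toy_psm_table()
        tight_keys = {g.key for g in apply_filter_cascade(table, tight).accepted_peptidoforms}
        loose_keys = {g.key for g in apply_filter_cascade(table, loose).accepted_peptidoforms}
        assert tight_keys <= loose_keys

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FilterConfig(max_combined_pep=0.0)
        with pytest.raises(ValueError):
            FilterConfig(min_spectra_per_peptidoform=0)
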