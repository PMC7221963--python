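import pytest

from teaphenol.spectral_annotation import (
    DEFAULT_LOSS_RULES,
    MsmsSpectrum,
    Peak,
    annotate_library,
    class_relative_abundance,
    classify_compound,
    detect_c_glycoside,
    detect_neutral_losses,
    identify_aglycone,
)
from teaphenol.synthetic_data import SimulationConfig, simulate_spectrum


def spectrum(precursor, peaks, **kw):
    return MsmsSpectrum(precursor, [Peak(mz, i) for mz, i in peaks], **kw)


NOISE_FREE = SimulationConfig(seed=1, precursor_ppm_sd=0.0, fragment_mda_sd=0.0,
                              n_decoy_peaks=0)


class TestDetectNeutralLosses:
    def test_galloyl_loss_from_precursor(self):
        # myricetin galloyl hexoside sheds the galloyl residue
        s = spectrum(631.0950, [(479.0853, 100.0)])
        hits = detect_neutral_losses(s)
        assert [a.rule.name for a in hits] == ["galloyl"]
        assert hits[0].delta == pytest.approx(152.0097, abs=1e-4)
        assert hits[0].from_precursor

    def test_precursor_only_spectrum_has_no_pairs(self):
        s = spectrum(289.0718, [(289.0718, 100.0)])
        assert detect_neutral_losses(s) == []

    def test_deoxyhexosyl_hexoside_chain(self):
        # rutinoside-type diglycoside peels off deoxyhexose then hexose
        s = spectrum(625.1410, [(479.0831, 50.0), (317.0303, 100.0)])
        names = {(a.rule.name, round(a.from_mz, 4)) for a in detect_neutral_losses(s)}
        assert ("deoxyhexose", 625.1410) in names
        assert ("hexose", 479.0831) in names

    def test_empty_rule_set_rejected(self):
        s = spectrum(289.0718, [(137.0244, 10.0)])
        with pytest.raises(ValueError):
            detect_neutral_losses(s, rules=[])

    def test_all_deltas_within_tolerance(self, library):
        tol = 0.02
        for entry in library:
            s = simulate_spectrum(entry, NOISE_FREE)
            for a in detect_neutral_losses(s, tol=tol):
                assert abs(a.delta - a.rule.exact_mass) <= tol


class TestIdentifyAglycone:
    def test_radical_dominance_reads_as_3_O(self):
        s = spectrum(463.0882, [(301.0367, 40.0), (300.0290, 100.0)])
        match = identify_aglycone(s)
        assert (match.name, match.evidence) == ("quercetin", "3-O")

    def test_even_electron_only_is_indeterminate(self):
        s = spectrum(479.0831, [(317.0303, 100.0)])
        match = identify_aglycone(s)
        assert (match.name, match.evidence) == ("myricetin", "indeterminate")

    def test_no_flavonoid_ion_gives_none(self):
        s = spectrum(341.1089, [(179.0560, 100.0), (161.0453, 20.0)])
        assert identify_aglycone(s) is None


class TestDetectCGlycoside:
    def test_cross_ring_loss_series(self):
        # apigenin di-C-glycoside: −60/−90/−120 from the precursor
        s = spectrum(563.1418, [(503.1225, 60.0), (473.1113, 100.0),
                                (443.1004, 80.0)])
        ok, evidence = detect_c_glycoside(s)
        assert ok and len(evidence) >= 2

    def test_o_glycoside_pattern_is_not_c_glycoside(self):
        s = spectrum(463.0887, [(301.0367, 40.0), (300.0290, 100.0)])
        ok, _ = detect_c_glycoside(s)
        assert not ok

    def test_single_cross_ring_loss_insufficient(self):
        s = spectrum(563.1418, [(443.1004, 80.0)])
        ok, _ = detect_c_glycoside(s)
        assert not ok

    def test_exclusive_with_o_glycoside_call(self, library):
        """A spectrum is never both a C-glycoside and an O-glycoside."""
        for entry in library:
            s = simulate_spectrum(entry, NOISE_FREE)
            result = classify_compound(s, precursor_formula=entry.formula)
            is_c, _ = detect_c_glycoside(s)
            if is_c:
                assert result.compound_class != "flavonol O-glycoside"


class TestClassifyCompound:
    def test_catechin_spectrum(self):
        s = spectrum(289.0722, [(245.0825, 30.0), (203.0719, 23.0),
                                (151.0407, 5.0), (137.0251, 2.0),
                                (125.0248, 7.0), (109.0300, 100.0)])
        result = classify_compound(s)
        assert result.compound_class == "flavan-3-ol"

    def test_coumaroyl_glycoside_with_radical_aglycone(self):
        # quercetin acyl triglycoside: coumaric acid / coumaroyl loss pair
        # and a dominant radical aglycone
        s = spectrum(917.2361, [(771.2075, 60.0), (753.1915, 40.0),
                                (301.0355, 30.0), (300.0277, 100.0)])
        result = classify_compound(s)
        assert result.compound_class == "acylated flavonol glycoside"
        assert result.aglycone == "quercetin"
        assert result.position_evidence == "3-O"
        assert result.flags.get("acyl_acid_pair")

    def test_noise_only_spectrum_unclassified(self):
        s = spectrum(500.0, [(97.1234, 1.0), (211.4567, 0.8), (333.3333, 0.5)])
        result = classify_compound(s)
        assert result.compound_class == "unclassified"
        assert result.score == 0.0

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            classify_compound(MsmsSpectrum(500.0, []))

    def test_intensity_scale_invariance(self, library):
        """Multiplying all intensities by a constant changes no class call."""
        for entry in library[::5]:
            s = simulate_spectrum(entry, SimulationConfig(seed=3))
            base = classify_compound(s, precursor_formula=entry.formula)
            for factor in (0.01, 7.0, 1e4):
                scaled = classify_compound(s.scaled(factor),
                                           precursor_formula=entry.formula)
                assert scaled.compound_class == base.compound_class

    def test_chain_never_reuses_a_peak(self, library):
        for entry in library:
            s = simulate_spectrum(entry, NOISE_FREE)
            result = classify_compound(s, precursor_formula=entry.formula)
            targets = [t for _, _, t, _ in result.loss_chain]
            assert len(targets) == len(set(targets))

    def test_noise_free_class_recovery(self, library):
        """Every library entry's class is recovered from its clean spectrum."""
        hits = sum(
            classify_compound(simulate_spectrum(e, NOISE_FREE),
                              precursor_formula=e.formula).compound_class
            == e.compound_class
            for e in library)
        assert hits == len(library)

    def test_score_bounded(self, library):
        for entry in library[::3]:
            s = simulate_spectrum(entry, SimulationConfig(seed=5))
            assert 0.0 <= classify_compound(s).score <= 1.0


class TestAnnotateLibrary:
    def test_round_trip_matches_rutin(self, library):
        entry = next(e for e in library if e.name == "rutin")
        s = simulate_spectrum(entry, NOISE_FREE)
        s = MsmsSpectrum(s.precursor_mz * (1 + 2e-6), s.peaks, rt=s.rt,
                         sample_id=s.sample_id)
        table = annotate_library([s], library)
        row = table.iloc[0]
        assert row["matched_peak_no"] == 27
        assert row["class"] == "flavonol O-glycoside"
        assert row["ppm"] == 2.0

    def test_out_of_library_precursor_unmatched(self, library):
        s = spectrum(5000.0, [(301.0354, 10.0), (300.0276, 100.0)])
        table = annotate_library([s], library)
        assert table.iloc[0]["matched_name"] is None
        assert table.iloc[0]["class"] is not None

    def test_noise_free_identity_round_trip(self, library):
        spectra = [simulate_spectrum(e, NOISE_FREE) for e in library]
        table = annotate_library(spectra, library)
        assert (table["matched_peak_no"].to_numpy()
                == [e.peak_no for e in library]).all()
        assert (table["ppm"] == 0.0).all()


class TestClassRelativeAbundance:
    def test_single_class(self):
        assert class_relative_abundance([("saccharide", 12.0)]) == {"saccharide": 100.0}

    def test_three_to_one_split(self):
        shares = class_relative_abundance([("a", 3.0), ("b", 1.0)])
        assert shares == {"a": 75.0, "b": 25.0}

    def test_percentages_sum_to_100(self):
        shares = class_relative_abundance(
            [("a", 1.7), ("b", 2.9), ("c", 0.4), ("a", 1.0)])
        assert sum(shares.values()) == pytest.approx(100.0, abs=1e-9)

    def test_planted_catechin_share_recovered(self):
        # panel built with an 89.9% catechin share by abundance
        pairs = [("flavan-3-ol", 89.9), ("flavonol O-glycoside", 6.1),
                 ("saccharide", 4.0)]
        shares = class_relative_abundance(pairs)
        assert shares["flavan-3-ol"] == pytest.approx(89.9, abs=0.1)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            class_relative_abundance([("a", 0.0)])


def test_loss_rule_masses_match_formulas():
    """Every rule's exact mass is derived from its own formula."""
    from teaphenol.formula_mass import monoisotopic_mass
    for rule in DEFAULT_LOSS_RULES:
        assert rule.exact_mass == monoisotopic_mass(rule.formula)
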