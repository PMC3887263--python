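"""Peak-list loading, assignment ranking, isotope fit, MS/MS interpretation."""

import pytest

import hostguest as hg
from hostguest.assign import STANDARD_LOSSES, NeutralLoss, nearest_miss


def ion(registry, label):
    return hg.parse_ion_label(label, registry)


class TestLoadPeaklist:
    def test_two_row_file(self, tmp_path):
        p = tmp_path / "peaks.csv"
        p.write_text("250.023,100\n272.005,80\n")
        s = hg.load_peaklist(p, "positive")
        assert [pk.mz for pk in s.peaks] == [250.023, 272.005]

    def test_header_and_bad_rows_skipped(self, tmp_path, caplog):
        p = tmp_path / "peaks.csv"
        p.write_text("mz,intensity\n250.023,100\nnot,a,number\n272.005,80\n")
        with caplog.at_level("WARNING"):
            s = hg.load_peaklist(p, "positive")
        assert len(s.peaks) == 2
        assert any(":3:" in r.message for r in caplog.records)

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(ValueError):
            hg.load_peaklist(p, "positive")

    def test_unsorted_input_is_sorted(self, tmp_path):
        p = tmp_path / "peaks.csv"
        p.write_text("500.0,1\n100.0,2\n300.0,3\n")
        s = hg.load_peaklist(p, "negative")
        assert [pk.mz for pk in s.peaks] == [100.0, 300.0, 500.0]

    def test_duplicate_mz_is_an_error(self, tmp_path):
        p = tmp_path / "peaks.csv"
        p.write_text("100.0,1\n100.0,2\n")
        with pytest.raises(ValueError):
            hg.load_peaklist(p, "positive")


class TestAssignPeaks:
    def test_complex_dianion_rank_one(self, default_config):
        s = hg.Spectrum("negative", (hg.Peak(690.682, 100.0),))
        cands = default_config.candidates("negative")
        best = hg.rank_one(hg.assign_peaks(s, cands))
        assert best[690.682].label == "[βCD + AlnH - 2H]2-"

    def test_unidentified_peak_stays_unassigned(self, default_config):
        s = hg.Spectrum("negative", (hg.Peak(1179.340, 100.0),))
        cands = default_config.candidates("negative")
        assignments = hg.assign_peaks(s, cands)
        assert assignments == []
        miss = nearest_miss(s.peaks[0], cands)
        assert abs(miss[1]) > 0.5  # nearest candidate is far away

    def test_exact_match_has_zero_delta(self, registry, default_config):
        target = ion(registry, "[AlnH + H]+")
        s = hg.Spectrum("positive", (hg.Peak(hg.mz_of_ion(target), 1.0),))
        best = hg.rank_one(
            hg.assign_peaks(s, default_config.candidates("positive"))
        )
        a = best[s.peaks[0].mz]
        assert a.label == "[AlnH + H]+"
        assert a.delta_m == pytest.approx(0.0, abs=1e-12)

    def test_doubling_tie_broken_by_parsimony(self, registry, default_config):
        # [M+H]+ and [2M+2H]2+ share an m/z; fewer components must win
        target = ion(registry, "[AlnH + H]+")
        s = hg.Spectrum("positive", (hg.Peak(hg.mz_of_ion(target), 1.0),))
        assignments = hg.assign_peaks(s, default_config.candidates("positive"))
        labels = [a.label for a in assignments if a.rank <= 2]
        assert labels == ["[AlnH + H]+", "[2AlnH + 2H]2+"]

    def test_polarity_mismatch_is_an_error(self, registry):
        s = hg.Spectrum("positive", (hg.Peak(250.0, 1.0),))
        with pytest.raises(ValueError):
            hg.assign_peaks(s, [ion(registry, "[AlnH - H]-")])

    def test_ranking_invariant_under_intensity_rescaling(self, default_config):
        from hostguest import reference as ref

        peaks1 = tuple(hg.Peak(mz, i) for mz, i, _ in ref.POSITIVE_PEAKS)
        peaks2 = tuple(hg.Peak(mz, i * 1234.5) for mz, i, _ in ref.POSITIVE_PEAKS)
        cands = default_config.candidates("positive")
        a1 = hg.assign_peaks(hg.Spectrum("positive", peaks1), cands)
        a2 = hg.assign_peaks(hg.Spectrum("positive", peaks2), cands)
        assert [(a.peak.mz, a.label, a.rank) for a in a1] == [
            (a.peak.mz, a.label, a.rank) for a in a2
        ]


class TestIsotopeFit:
    def _simulated(self, registry, label, seed=3):
        truth = hg.SpectrumTruth(
            species=((ion(registry, label), 1.0),),
            jitter_ppm=0.0,
            n_isotopologues=4,
            seed=seed,
        )
        return hg.simulate_spectrum(truth)[0]

    def test_self_match_scores_near_one(self, registry, default_config):
        s = self._simulated(registry, "[βCD + AlnH + 2H]2+")
        best = hg.rank_one(
            hg.assign_peaks(s, default_config.candidates("positive"))
        )
        a = best[s.peaks[0].mz]
        assert a.label == "[βCD + AlnH + 2H]2+"
        assert hg.isotope_fit(s, a) >= 0.999

    def test_wrong_charge_hypothesis_scores_low(self, registry, default_config):
        # spectrum of a z=1 species; the z=2 doubled-formula hypothesis has
        # the same monoisotopic m/z but half the isotopologue spacing
        s = self._simulated(registry, "[AlnH + H]+")
        assignments = hg.assign_peaks(s, default_config.candidates("positive"))
        by_label = {a.label: a for a in assignments if a.peak.mz == s.peaks[0].mz}
        assert hg.isotope_fit(s, by_label["[AlnH + H]+"]) >= 0.999
        assert hg.isotope_fit(s, by_label["[2AlnH + 2H]2+"]) < 0.5

    def test_missing_partner_penalized_for_large_formulas(
        self, registry, default_config
    ):
        # a lone peak claimed to be a 42-carbon ion (A+1/A ≈ 0.47) with no
        # visible A+1 partner must score near zero
        target = ion(registry, "[βCD + H]+")
        s = hg.Spectrum("positive", (hg.Peak(hg.mz_of_ion(target), 100.0),))
        best = hg.rank_one(
            hg.assign_peaks(s, default_config.candidates("positive"))
        )
        assert hg.isotope_fit(s, best[s.peaks[0].mz]) == pytest.approx(0.0)


class TestMsms:
    def test_protonated_guest_ladder(self, registry):
        precursor = ion(registry, "[AlnH + H]+")
        s = hg.Spectrum(
            "positive",
            (hg.Peak(168.041, 50.0), hg.Peak(150.031, 30.0), hg.Peak(86.059, 20.0)),
            precursor=precursor,
        )
        anns = hg.interpret_msms(precursor, s)
        chains = {round(a.peak.mz, 3): a.chain.losses for a in anns}
        assert chains[168.041] == ("H3PO3",)
        assert chains[150.031] == ("H3PO3", "H2O")
        assert chains[86.059] == ("H3PO3", "H2O", "HPO2")

    def test_deprotonated_guest_depth_two(self, registry):
        precursor = ion(registry, "[AlnH - H]-")
        s = hg.Spectrum("negative", (hg.Peak(148.018, 10.0),))
        anns = hg.interpret_msms(precursor, s)
        assert anns[0].chain.losses == ("H3PO3", "H2O")
        assert anns[0].chain.mz == pytest.approx(148.0169, abs=1e-3)

    def test_glucose_ladder_spacing(self, registry):
        # sequential glucose-unit losses from the protonated host
        precursor = ion(registry, "[βCD + H]+")
        glc = NeutralLoss.from_string("Glc", "C6H10O5")
        start = hg.mz_of_ion(precursor)
        peaks = tuple(
            hg.Peak(start - k * 162.0528, 10.0) for k in range(1, 5)
        )
        anns = hg.interpret_msms(
            precursor, hg.Spectrum("positive", peaks), [glc], max_depth=4
        )
        assert len(anns) == 4
        for k, ann in enumerate(anns, start=1):
            assert ann.chain.losses == ("Glc",) * k

    def test_multiply_charged_precursor_rejected(self, registry):
        precursor = ion(registry, "[βCD + AlnH + 2H]2+")
        s = hg.Spectrum("positive", (hg.Peak(100.0, 1.0),))
        with pytest.raises(ValueError):
            hg.interpret_msms(precursor, s)

    def test_chains_are_mass_consistent(self, registry):
        from hostguest.assign import expand_loss_chains
        from hostguest.formula import monoisotopic_mass

        precursor = ion(registry, "[AlnH + H]+")
        pre_mz = hg.mz_of_ion(precursor)
        for chain in expand_loss_chains(precursor, STANDARD_LOSSES, max_depth=3):
            lost = sum(
                monoisotopic_mass(loss.formula)
                for loss in STANDARD_LOSSES
                for _ in range(chain.losses.count(loss.name))
            )
            assert chain.mz == pytest.approx(pre_mz - lost, abs=1e-9)

    def test_impossible_loss_pruned_silently(self, registry):
        # glucose loss cannot come out of the bisphosphonate guest
        precursor = ion(registry, "[AlnH + H]+")
        s = hg.Spectrum("positive", (hg.Peak(88.0, 1.0),))
        anns = hg.interpret_msms(
            precursor, s, [NeutralLoss.from_string("Glc", "C6H10O5")]
        )
        assert anns == []
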