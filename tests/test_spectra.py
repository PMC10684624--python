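"""Peak-list I/O, averaging, annotation, EI fragments, efficiency."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from silylms import (
    ADDUCTS,
    EfficiencyReport,
    PeakList,
    PeakListError,
    annotate,
    average_spectra,
    derivatization_ratio,
    derivatized_formula,
    efficiency_factor,
    mz,
    parse_formula,
    predict_ei_fragments,
    read_peaklist,
    round_2sf,
    write_peaklist,
)


def make_peaklist(pairs, **kw):
    return PeakList.from_pairs(pairs, **kw)


class TestPeakListContainer:
    def test_invariants_enforced(self):
        with pytest.raises(PeakListError):
            PeakList(mz=[100.0, 99.0], intensity=[1.0, 1.0])
        with pytest.raises(PeakListError):
            PeakList(mz=[100.0, 101.0], intensity=[1.0, -1.0])
        with pytest.raises(PeakListError):
            PeakList(mz=[100.0, 101.0], intensity=[1.0])

    def test_from_pairs_sorts_and_merges(self):
        p = make_peaklist([(200.0, 1.0), (100.0, 2.0), (100.0, 3.0)])
        assert p.mz.tolist() == [100.0, 200.0]
        assert p.intensity.tolist() == [5.0, 1.0]


class TestIO:
    def test_csv_roundtrip(self, tmp_path):
        p = make_peaklist([(100.1234, 10.0), (200.5678, 20.0), (300.0, 5.0)])
        path = tmp_path / "peaks.csv"
        write_peaklist(p, path)
        q = read_peaklist(path)
        np.testing.assert_allclose(q.mz, p.mz, atol=1e-6)
        np.testing.assert_allclose(q.intensity, p.intensity, atol=1e-6)

    def test_csv_requires_header(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("100.0,10\n200.0,20\n")
        with pytest.raises(PeakListError):
            read_peaklist(path)

    def test_msp_roundtrip(self, tmp_path):
        p = make_peaklist(
            [(73.0, 40.0), (857.0, 20.0)],
            mode="EI", resolution="unit", metadata={"compound_name": "test"},
        )
        path = tmp_path / "spec.msp"
        write_peaklist(p, path)
        q = read_peaklist(path, mode="EI", resolution="unit")
        assert len(q) == 2
        np.testing.assert_allclose(q.mz, p.mz)
        np.testing.assert_allclose(q.intensity, p.intensity)

    def test_msp_num_peaks(self, tmp_path):
        path = tmp_path / "nist.msp"
        path.write_text(
            "Name: demo\nNum Peaks: 2\n100.0 10.0\n200.0 20.0\n\n"
        )
        q = read_peaklist(path)
        assert len(q) == 2


class TestAveraging:
    def test_single_scan_identity(self):
        p = make_peaklist([(100.0, 10.0), (200.0, 5.0)])
        avg = average_spectra([p])
        np.testing.assert_allclose(avg.mz, p.mz)
        np.testing.assert_allclose(avg.intensity, p.intensity)

    @given(st.integers(1, 6))
    def test_n_copies_equal_one_scan(self, n):
        p = make_peaklist([(100.0, 10.0), (250.5, 40.0), (500.1, 3.0)])
        avg = average_spectra([p] * n)
        np.testing.assert_allclose(avg.mz, p.mz, atol=1e-12)
        np.testing.assert_allclose(avg.intensity, p.intensity, atol=1e-12)

    def test_weighted_merge_across_scans(self):
        a = make_peaklist([(100.000, 10.0)])
        b = make_peaklist([(100.001, 30.0)])
        avg = average_spectra([a, b], bin_tolerance=5.0)
        assert len(avg) == 1
        assert avg.mz[0] == pytest.approx(100.00075, abs=1e-9)
        assert avg.intensity[0] == pytest.approx(20.0)

    def test_absent_peak_counts_as_zero(self):
        a = make_peaklist([(100.0, 10.0), (200.0, 8.0)])
        b = make_peaklist([(100.0, 30.0)])
        avg = average_spectra([a, b], bin_tolerance=5.0)
        assert avg.intensity.tolist() == [20.0, 4.0]

    def test_mixed_modes_rejected(self):
        a = make_peaklist([(100.0, 1.0)], mode="EI")
        b = make_peaklist([(100.0, 1.0)], mode="ESI-pos")
        with pytest.raises(ValueError):
            average_spectra([a, b])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            average_spectra([])


class TestAnnotate:
    def test_tbutyl_loss_matches_at_unit_resolution(self, ted13, tbdms):
        """TED 13 + 3 TBDMS loses t-butyl: 616 - 57 = 559, matching the
        observed 559.35 within 0.5 Da."""
        species = derivatized_formula(ted13, tbdms, 3)
        preds = predict_ei_fragments(species, tbdms, resolution="nominal")
        p = make_peaklist([(559.35, 50.0)], mode="EI", resolution="unit")
        report = annotate(p, preds)
        matched = {a.species_label for a in report}
        assert any("t-butyl" in lbl for lbl in matched)

    def test_methyl_loss_of_underivatized_unknown(self, ztf_parent, tbdms):
        preds = predict_ei_fragments(ztf_parent, tbdms, resolution="nominal")
        p = make_peaklist([(363.0, 100.0)], mode="EI", resolution="unit")
        report = annotate(p, preds)
        assert [a.predicted_mz for a in report] == [363.0]

    def test_empty_peaklist_zero_annotations(self):
        p = PeakList(mz=np.array([]), intensity=np.array([]))
        report = annotate(p, [("x", 100.0)])
        assert len(report) == 0 and report.unmatched == (("x", 100.0),)

    def test_tolerance_monotone(self):
        p = make_peaklist([(100.003, 5.0), (100.010, 9.0)])
        preds = [("a", 100.0), ("b", 100.009)]
        prev = None
        for tol in (0.02, 0.01, 0.005, 0.002, 0.0005):
            got = {a.species_label for a in annotate(p, preds, tolerance=tol)}
            if prev is not None:
                assert got <= prev
            prev = got

    def test_equidistant_tie_goes_to_more_intense(self):
        p = make_peaklist([(99.99, 5.0), (100.01, 50.0)])
        [a] = annotate(p, [("x", 100.0)], tolerance=0.05).annotations
        assert a.peak_index == 1


class TestEIFragments:
    def test_pentakis_tbdms_quercetin_nominal(self, quercetin, tbdms):
        species = derivatized_formula(quercetin, tbdms, 5)
        mzs = {v for _, v in predict_ei_fragments(species, tbdms, "nominal")}
        assert mzs == {872.0, 857.0, 815.0}

    def test_silylated_species_has_exactly_m_m15_m57(self, ted13, tbdms):
        for d in (1, 2, 3):
            species = derivatized_formula(ted13, tbdms, d)
            got = sorted(v for _, v in predict_ei_fragments(species, tbdms, "nominal"))
            m = species.nominal_mass
            assert got == [m - 57, m - 15, m]

    def test_underivatized_si_free_species(self, quercetin, tbdms):
        got = predict_ei_fragments(quercetin, tbdms, "nominal")
        assert [v for _, v in got] == [302.0, 287.0]  # [M]+. and generic -CH3

    def test_unsubtractable_loss_warns_and_omits(self, tbdms):
        species = parse_formula("CH2Si")  # H too poor for a t-butyl loss
        with pytest.warns(UserWarning):
            got = predict_ei_fragments(species, tbdms, "nominal")
        assert len(got) >= 1

    def test_tms_reporter_ion(self, tms):
        species = parse_formula("C9H14OSi")
        got = dict(predict_ei_fragments(species, tms, "accurate"))
        assert got["TMS+ reporter"] == pytest.approx(73.0468, abs=1e-3)


class TestEfficiency:
    def _spectrum(self, parent, tbdms, degree_intensity):
        rule = ADDUCTS["[M-H]-"]
        pairs = [
            (mz(derivatized_formula(parent, tbdms, d), rule), i)
            for d, i in degree_intensity.items()
        ]
        return make_peaklist(pairs, mode="ESI-neg")

    def test_ratio_by_construction(self, quercetin, tbdms):
        p = self._spectrum(quercetin, tbdms, {0: 908.0, 4: 100.0})
        rep = derivatization_ratio(p, quercetin, tbdms, [ADDUCTS["[M-H]-"]], 5)
        assert rep.ratio == pytest.approx(9.08)

    def test_complete_derivatization_flag(self, quercetin, tbdms):
        p = self._spectrum(quercetin, tbdms, {4: 100.0})
        rep = derivatization_ratio(p, quercetin, tbdms, [ADDUCTS["[M-H]-"]], 5)
        assert rep.ratio == 0.0 and rep.complete_derivatization

    def test_absent_derivatized_signal_is_undefined(self, quercetin, tbdms):
        p = self._spectrum(quercetin, tbdms, {0: 100.0})
        rep = derivatization_ratio(p, quercetin, tbdms, [ADDUCTS["[M-H]-"]], 5)
        assert rep.ratio is None and rep.no_derivatized_signal

    @given(st.floats(0.1, 100.0))
    def test_scale_invariance(self, scale):
        import silylms

        quercetin = silylms.parse_formula("C15H10O7")
        tbdms = silylms.get_reagent("TBDMS")
        p = self._spectrum(quercetin, tbdms, {0: 908.0, 4: 100.0})
        scaled = PeakList(mz=p.mz, intensity=p.intensity * scale, mode=p.mode)
        r1 = derivatization_ratio(p, quercetin, tbdms, [ADDUCTS["[M-H]-"]], 5)
        r2 = derivatization_ratio(scaled, quercetin, tbdms, [ADDUCTS["[M-H]-"]], 5)
        assert r1.ratio == pytest.approx(r2.ratio)

    @pytest.mark.parametrize(
        "batch,flow,raw,sf2",
        [
            ((908.0, 100.0), (36.6, 100.0), 24.81, 25.0),
            ((100.0, 100.0), (100.0, 100.0), 1.0, 1.0),
            ((100.0, 100.0), (50.0, 100.0), 2.0, 2.0),
        ],
    )
    def test_efficiency_factor(self, batch, flow, raw, sf2):
        b = EfficiencyReport(*batch, label="batch")
        f = EfficiencyReport(*flow, label="flow")
        fac = efficiency_factor(b, f)
        assert fac.raw == pytest.approx(raw, abs=0.01)
        assert fac.rounded_2sf == sf2

    def test_factor_undefined_when_flow_has_no_derivatized_signal(self):
        b = EfficiencyReport(908.0, 100.0, label="batch")
        f = EfficiencyReport(100.0, 0.0, label="flow")
        assert efficiency_factor(b, f).undefined

    def test_round_2sf(self):
        assert round_2sf(24.80874) == 25.0
        assert round_2sf(0.03662) == 0.037
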