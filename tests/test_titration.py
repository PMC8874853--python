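"""Domain types, inner-filter correction, and CSV/report round trips."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import quenchbind as qb
from quenchbind import simulate as sim
from quenchbind.errors import FormatError, InputDomainError


class TestInnerFilter:
    @pytest.mark.parametrize(
        "f_obs, a_ex, a_em, expected",
        [
            (100.0, 0.0, 0.0, 100.0),                    # zero absorbance is identity
            (100.0, 0.1, 0.1, 100.0 * math.exp(0.1)),    # 110.517...
            (50.0, 1.0, 1.0, 50.0 * math.e),             # 135.914...
        ],
    )
    def test_correction_values(self, f_obs, a_ex, a_em, expected):
        assert qb.correct_inner_filter(f_obs, a_ex, a_em) == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize(
        "f_obs, a_ex, a_em",
        [(-1.0, 0.1, 0.1), (0.0, 0.1, 0.1), (100.0, -0.1, 0.1), (100.0, 0.1, -0.1)],
    )
    def test_domain_errors(self, f_obs, a_ex, a_em):
        with pytest.raises(InputDomainError):
            qb.correct_inner_filter(f_obs, a_ex, a_em)

    @given(
        f=st.floats(1e-3, 1e6),
        a1=st.floats(0, 3),
        a2=st.floats(0, 3),
        da=st.floats(1e-6, 1),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_never_decreases_and_strictly_increasing(self, f, a1, a2, da):
        base = qb.correct_inner_filter(f, a1, a2)
        assert base >= f
        assert qb.correct_inner_filter(f, a1 + da, a2) > base
        assert qb.correct_inner_filter(f, a1, a2 + da) > base


class TestTitrationSeries:
    def test_requires_zero_first_point(self):
        with pytest.raises(InputDomainError):
            qb.TitrationSeries("x", [1.0, 2.0], [100.0, 90.0], 298.0)

    @pytest.mark.parametrize(
        "conc, inten",
        [
            ([0.0, 2.0, 1.0], [100.0, 90.0, 80.0]),   # not increasing
            ([0.0, 1.0, 1.0], [100.0, 90.0, 80.0]),   # duplicate
            ([0.0, 1.0, 2.0], [100.0, -1.0, 80.0]),   # non-positive intensity
            ([0.0, 1.0], [100.0, 90.0, 80.0]),        # length mismatch
        ],
    )
    def test_invariant_violations(self, conc, inten):
        with pytest.raises(InputDomainError):
            qb.TitrationSeries("x", conc, inten, 298.0)

    def test_molar_conversion_is_a_view_not_a_mutation(self):
        s = qb.TitrationSeries("x", [0.0, 1.0, 2.0, 3.0], [100.0, 90.0, 80.0, 70.0], 298.0)
        m1 = s.ligand_conc_molar
        m2 = s.ligand_conc_molar
        np.testing.assert_allclose(m1, np.array([0, 1, 2, 3]) * 1e-6)
        np.testing.assert_array_equal(m1, m2)  # repeated access never re-scales
        np.testing.assert_array_equal(s.ligand_conc, [0, 1, 2, 3])

    def test_f0_uses_corrected_intensity(self):
        s = qb.TitrationSeries(
            "x", [0.0, 1.0, 2.0], [100.0, 90.0, 80.0], 298.0,
            a_ex=[0.1, 0.1, 0.1], a_em=[0.1, 0.1, 0.1],
        )
        assert s.ife_applied
        assert s.f0 == pytest.approx(100.0 * math.exp(0.1))


class TestTitrationCsv:
    def _write(self, tmp_path, text, name="t.csv"):
        p = tmp_path / name
        p.write_text(text)
        return p

    def test_round_trip_lossless(self, tmp_path, static_series):
        p = tmp_path / "series.csv"
        qb.write_titration_csv(static_series, p)
        back = qb.read_titration_csv(p, temperature=static_series.temperature)
        np.testing.assert_allclose(back.ligand_conc, static_series.ligand_conc, rtol=1e-9)
        np.testing.assert_allclose(back.intensity_obs, static_series.intensity_obs, rtol=1e-9)
        assert back.n_points() == 12

    def test_missing_intensity_column(self, tmp_path):
        p = self._write(tmp_path, "conc_uM,foo\n0,1\n1,2\n")
        with pytest.raises(FormatError, match="F_obs"):
            qb.read_titration_csv(p, temperature=298.0)

    def test_non_numeric_cell_names_row(self, tmp_path):
        p = self._write(tmp_path, "conc_uM,F_obs\n0,100\n1,oops\n2,80\n")
        with pytest.raises(FormatError, match="line 3"):
            qb.read_titration_csv(p, temperature=298.0)

    def test_duplicate_concentration_rejected(self, tmp_path):
        p = self._write(tmp_path, "conc_uM,F_obs\n0,100\n1,90\n1,85\n")
        with pytest.raises(FormatError, match="duplicate"):
            qb.read_titration_csv(p, temperature=298.0)

    def test_rows_sorted_and_comments_skipped(self, tmp_path):
        p = self._write(tmp_path, "# a comment\nconc_uM,F_obs\n2,80\n0,100\n1,90\n")
        s = qb.read_titration_csv(p, temperature=298.0)
        np.testing.assert_array_equal(s.ligand_conc, [0, 1, 2])

    def test_absorbance_columns_enable_correction(self, tmp_path):
        p = self._write(
            tmp_path,
            "conc_uM,F_obs,A_ex,A_em\n0,100,0.02,0.01\n1,90,0.05,0.02\n2,80,0.09,0.03\n",
        )
        s = qb.read_titration_csv(p, temperature=298.0)
        assert s.ife_applied
        assert np.all(s.intensity >= s.intensity_obs)

    def test_lonely_absorbance_column_rejected(self, tmp_path):
        p = self._write(tmp_path, "conc_uM,F_obs,A_ex\n0,100,0.1\n1,90,0.1\n")
        with pytest.raises(FormatError):
            qb.read_titration_csv(p, temperature=298.0)


class TestReportIO:
    def test_quenching_result_round_trip(self, tmp_path, dynamic_series):
        res = qb.stern_volmer_fit(dynamic_series)
        doc = qb.write_report({"quenching": [res]}, tmp_path / "r.json")
        back = qb.read_report(tmp_path / "r.json")
        assert back == doc
        entry = back["quenching"][0]
        assert entry["ksv"] == pytest.approx(res.ksv, rel=1e-9)
        assert entry["kq"] == pytest.approx(res.kq, rel=1e-9)
        assert entry["_type"] == "QuenchingResult"

    def test_empty_report_has_all_sections(self, tmp_path):
        qb.write_report({}, tmp_path / "empty.json")
        back = qb.read_report(tmp_path / "empty.json")
        for section in ("quenching", "binding", "thermodynamics", "competition",
                        "spectral_features"):
            assert back[section] == []

    def test_full_analysis_report_contains_all_blocks(self, tmp_path, static_series):
        sets = sim.generate_vant_hoff_set(-100.0, -200.0, [298.0, 303.0, 310.0])
        binding = [qb.double_log_fit(s) for s, _ in sets]
        thermo = qb.vant_hoff_fit([(b.temperature, b.kb) for b in binding])
        sv = qb.stern_volmer_fit(static_series)
        free, bound = sim.generate_emission_pair()
        shift = qb.peak_shift(free, bound)
        tern, _ = sim.generate_titration(
            sim.GroundTruth(kb=2.07e4, competitor_k=6.33e6, competitor_conc=5.5)
        )
        comp = qb.compare_systems(
            (sv, qb.double_log_fit(static_series), static_series),
            (qb.stern_volmer_fit(tern), qb.double_log_fit(tern), tern),
        )
        doc = qb.write_report(
            {
                "quenching": [sv],
                "binding": binding,
                "thermodynamics": [thermo],
                "competition": [comp],
                "spectral_features": [shift],
            },
            tmp_path / "full.json",
            provenance={"label": "synthetic", "temperature": 298.0},
        )
        for section in ("quenching", "binding", "thermodynamics", "competition",
                        "spectral_features"):
            assert doc[section], f"section {section} empty"

    def test_unknown_section_rejected(self, tmp_path):
        with pytest.raises(InputDomainError):
            qb.write_report({"docking": []}, tmp_path / "x.json")
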