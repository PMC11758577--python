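import numpy as np
import pytest

from nanoscint.atomic_data import (
    EnergyOutOfRangeError,
    Material,
    MATERIALS,
    TableFormatError,
    csda_range,
    electron_stopping,
    linear_attenuation,
    load_element_table,
    make_toy_tables,
    mass_attenuation,
    save_element_table,
)


class TestShippedTables:
    def test_zn_k_edge_rounds_to_9_7(self, library):
        assert round(library["Zn"].k_edge, 1) == 9.7

    def test_k_edge_jump_is_discontinuous(self, library):
        zn = library["Zn"]
        assert zn.k_jump_ratio > 1.0
        below = zn.interpolate(zn.k_edge * (1 - 1e-9), "photoelectric")
        above = zn.interpolate(zn.k_edge, "photoelectric")
        assert above / below > 1.0

    def test_all_elements_valid(self, library):
        assert set(library) == {"H", "C", "N", "O", "Si", "Ar", "Zn"}
        for rec in library.values():
            assert 0.0 <= rec.fluorescence_yield_k <= 1.0
            assert np.all(rec.photon_table[:, 1:] > 0)

    def test_total_is_sum_of_channels(self, library):
        for name in ("SiO2", "ZnO", "air", "TCPP"):
            mat = MATERIALS[name]
            for e in (0.3, 1.0, 3.3, 6.6, 9.659, 10.0, 14.9):
                total = mass_attenuation(mat, e, "total", library)
                parts = sum(
                    mass_attenuation(mat, e, c, library)
                    for c in ("photoelectric", "incoherent", "coherent"))
                assert total == pytest.approx(parts, rel=1e-12)


class TestLoader:
    def test_toy_round_trip(self, toy_library, tmp_path):
        rec = toy_library["X30"]
        p, _ = save_element_table(rec, tmp_path)
        rec2 = load_element_table(p)
        assert rec2.atomic_number == rec.atomic_number
        assert rec2.k_edge == pytest.approx(rec.k_edge)
        assert rec2.fluorescence_yield_k == pytest.approx(
            rec.fluorescence_yield_k)
        np.testing.assert_allclose(rec2.photon_table, rec.photon_table,
                                   rtol=1e-5)
        np.testing.assert_allclose(rec2.electron_table, rec.electron_table,
                                   rtol=1e-5)

    def test_single_row_rejected(self, tmp_path):
        p = tmp_path / "X1.csv"
        p.write_text(
            "# element=X1 Z=1 mass=2 k_edge_keV=0.01 l_edge_keV=0.001 "
            "kalpha_keV=0.005 omega_k=0\n"
            "energy_keV,pe_cm2g,incoh_cm2g,coh_cm2g\n"
            "1,1,1,1\n")
        (tmp_path / "X1_electron.csv").write_text(
            "energy_keV,stopping_MeVcm2g\n0.25,10\n15,1\n")
        with pytest.raises(TableFormatError, match="too short"):
            load_element_table(p)

    def test_non_monotone_grid_rejected_with_row(self, tmp_path):
        p = tmp_path / "X1.csv"
        p.write_text(
            "# element=X1 Z=1 mass=2 k_edge_keV=0.01 l_edge_keV=0.001 "
            "kalpha_keV=0.005 omega_k=0\n"
            "energy_keV,pe_cm2g,incoh_cm2g,coh_cm2g\n"
            "1,1,1,1\n3,1,1,1\n2,1,1,1\n")
        (tmp_path / "X1_electron.csv").write_text(
            "energy_keV,stopping_MeVcm2g\n0.25,10\n15,1\n")
        with pytest.raises(TableFormatError, match="data row 3"):
            load_element_table(p)

    def test_malformed_header_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("energy_keV,pe_cm2g,incoh_cm2g,coh_cm2g\n1,1,1,1\n")
        with pytest.raises(TableFormatError, match="header"):
            load_element_table(p)


class TestMassAttenuation:
    def test_single_element_at_grid_node_is_exact(self, library):
        zn = library["Zn"]
        pure = Material("pureZn", 7.14, {"Zn": 1.0})
        i = 10
        e = zn.photon_table[i, 0]
        assert mass_attenuation(pure, e, "photoelectric", library) == \
            pytest.approx(zn.photon_table[i, 1], rel=1e-12)

    def test_midpoint_matches_brute_force_loglog(self, library):
        # independent oracle: recompute the log-log interpolation by hand
        rec = library["Si"]
        tbl = rec.photon_table
        i = 20
        e0, e1 = tbl[i, 0], tbl[i + 1, 0]
        e = np.sqrt(e0 * e1)
        for col, channel in ((1, "photoelectric"), (2, "incoherent"),
                             (3, "coherent")):
            t = np.log(e / e0) / np.log(e1 / e0)
            expected = np.exp((1 - t) * np.log(tbl[i, col])
                              + t * np.log(tbl[i + 1, col]))
            got = rec.interpolate(e, channel)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_zn_pe_above_edge_exceeds_below(self, library):
        mat = MATERIALS["ZnO"]
        below = mass_attenuation(mat, 9.658, "photoelectric", library)
        above = mass_attenuation(mat, 9.660, "photoelectric", library)
        assert above > below * 4  # strong K-edge enhancement

    def test_out_of_range_raises(self, library):
        with pytest.raises(EnergyOutOfRangeError):
            mass_attenuation(MATERIALS["SiO2"], 0.01, "total", library)
        with pytest.raises(EnergyOutOfRangeError):
            mass_attenuation(MATERIALS["SiO2"], 200.0, "total", library)

    def test_interpolation_monotone_between_monotone_nodes(self, library):
        rec = library["O"]
        tbl = rec.photon_table
        i = 15
        es = np.linspace(tbl[i, 0], tbl[i + 1, 0], 20)
        vals = rec.interpolate(es, "photoelectric")
        # photoelectric decreases with energy away from edges
        assert np.all(np.diff(vals) < 0)


class TestLinearAttenuation:
    def test_density_zero_gives_zero(self, library):
        m = Material("void", 0.0, {"Si": 0.4674, "O": 0.5326})
        assert linear_attenuation(m, 5.0, "total", library) == 0.0

    def test_zno_unit_conversion(self, library):
        mat = MATERIALS["ZnO"]
        for e in (3.3, 6.6, 10.0):
            assert linear_attenuation(mat, e, "total", library) == \
                pytest.approx(
                    mass_attenuation(mat, e, "total", library) * 5.61e-7,
                    rel=1e-12)

    def test_linearity_in_density(self, library):
        m1 = Material("a", 1.0, {"O": 1.0})
        m2 = Material("b", 2.0, {"O": 1.0})
        assert linear_attenuation(m2, 4.0, "total", library) == \
            pytest.approx(2 * linear_attenuation(m1, 4.0, "total", library))


class TestElectronStopping:
    def test_grid_node_with_density_conversion(self, library):
        rec = library["Si"]
        pure = Material("si", 2.33, {"Si": 1.0})
        e = rec.electron_table[5, 0]
        expected = rec.electron_table[5, 1] * 2.33 * 1e3 * 1e-7
        assert electron_stopping(pure, e, library) == \
            pytest.approx(expected, rel=1e-12)

    def test_positive_over_full_grid(self, library):
        grid = np.geomspace(0.25, 15.0, 50)
        s = electron_stopping(MATERIALS["SiO2"], grid, library)
        assert np.all(s > 0)

    def test_below_cutoff_raises(self, library):
        with pytest.raises(EnergyOutOfRangeError):
            electron_stopping(MATERIALS["SiO2"], 0.1, library)

    def test_csda_range_matches_fine_quadrature(self, library):
        # oracle: independent fine-grid trapezoid of 1/S
        mat = MATERIALS["SiO2"]
        e = 5.0
        grid = np.geomspace(0.25, e, 20000)
        fine = np.trapezoid(1.0 / electron_stopping(mat, grid, library),
                            grid)
        assert csda_range(mat, e, library) == pytest.approx(fine, rel=0.01)


class TestToyTables:
    def test_jump_ratio_one_rejected(self, tmp_path):
        grid = list(np.geomspace(0.25, 15, 30))
        with pytest.raises(ValueError, match="jump_ratio"):
            make_toy_tables([(10, 2.0, 1.0)], grid, tmp_path)

    def test_inverse_cube_law_below_edge(self, toy_library):
        # files carry 6 significant digits, hence the tolerance
        rec = toy_library["X30"]
        v1 = rec.interpolate(1.0, "photoelectric")
        v2 = rec.interpolate(2.0, "photoelectric")
        assert v1 / v2 == pytest.approx(8.0, rel=1e-5)

    def test_requested_edge_round_trips(self, toy_library):
        assert toy_library["X30"].k_edge == pytest.approx(9.5)
        assert toy_library["X30"].k_jump_ratio == pytest.approx(6.0, rel=1e-6)
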