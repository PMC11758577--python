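import math

import numpy as np
import pytest

from nanoscint.geometry import (
    AssemblyConfig,
    Body,
    PlacementError,
    build_code_a,
    build_code_b,
    equal_volume_shell_thickness,
    export_bodies_csv,
    locate,
    ray_segments,
    sphere_volume,
    zno_total_volume,
)


class TestClosedForms:
    def test_total_np_volume(self):
        # 215 spheres of 5 nm diameter
        assert zno_total_volume(215, 5.0) == pytest.approx(
            215 * math.pi / 6 * 125, rel=1e-12)

    def test_equal_volume_shell_thickness(self):
        t = equal_volume_shell_thickness(80.0, 215, 5.0)
        assert t == pytest.approx(0.688, abs=5e-4)
        assert round(t, 1) == 0.7


class TestCodeA:
    def test_zero_nps_single_body(self):
        model = build_code_a(AssemblyConfig(code="A", n_zno=0, seed=0))
        assert len(model.bodies) == 1
        assert model.bodies[0].medium == "SiO2"

    def test_215_nps_placed_without_overlap(self, code_a_model):
        nps = [b for b in code_a_model.bodies if b.medium == "ZnO"]
        assert len(nps) == 215
        centers = np.array([b.center for b in nps])
        # tangent placement on the 42.5 nm sphere
        np.testing.assert_allclose(np.linalg.norm(centers, axis=1), 42.5,
                                   rtol=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_pairwise_min_distance_brute_force(self, seed):
        model = build_code_a(AssemblyConfig(code="A", n_zno=100, seed=seed))
        centers = np.array([b.center for b in model.bodies
                            if b.medium == "ZnO"])
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        d[np.diag_indices_from(d)] = np.inf
        assert d.min() >= 5.0 - 1e-9

    def test_determinism_and_seed_sensitivity(self):
        cfg = AssemblyConfig(code="A", n_zno=50)
        a = build_code_a(cfg, seed=7)
        b = build_code_a(cfg, seed=7)
        c = build_code_a(cfg, seed=8)
        ca = np.array([x.center for x in a.bodies])
        cb = np.array([x.center for x in b.bodies])
        cc = np.array([x.center for x in c.bodies])
        assert np.array_equal(ca, cb)
        assert not np.array_equal(ca, cc)


class TestCodeB:
    def test_single_nanosystem_is_core_plus_shell(self):
        model = build_code_b(AssemblyConfig(code="B", n_nanosystems=1,
                                            seed=0))
        assert len(model.bodies) == 2
        core, shell = model.bodies
        assert core.medium == "SiO2" and shell.medium == "ZnO"
        assert core.center == shell.center
        assert shell.radii == (40.0, pytest.approx(40.6877, abs=1e-3))

    def test_shell_volume_matches_215_nps(self):
        model = build_code_b(AssemblyConfig(code="B", n_nanosystems=1,
                                            seed=0))
        shell = model.bodies[1]
        assert shell.volume == pytest.approx(zno_total_volume(), rel=0.03)

    def test_full_population_spacing_statistics(self):
        # 5e4 coated spheres in the downscaled holder: no overlaps, and a
        # characteristic surface-to-surface spacing of order tens of nm
        from scipy.spatial import cKDTree

        model = build_code_b(AssemblyConfig(code="B", n_nanosystems=50_000,
                                            seed=3))
        centers = np.array([b.center for b in model.bodies
                            if b.shape == "sphere"])
        assert len(centers) == 50_000
        tree = cKDTree(centers)
        dist, _ = tree.query(centers, k=2)
        gap = dist[:, 1] - 2 * 40.6877
        assert gap.min() >= -1e-6  # hard non-overlap
        # characteristic inter-particle spacing from the number density
        v_holder = math.pi * 4250.0**2 * 1000.0
        spacing = (v_holder / 50_000) ** (1 / 3) - 2 * 40.6877
        assert 10.0 < spacing < 100.0

    def test_infeasible_packing_raises(self):
        with pytest.raises(PlacementError):
            build_code_b(AssemblyConfig(
                code="B", n_nanosystems=10_000, holder_diameter_um=0.5,
                holder_height_um=0.2, seed=0))

    def test_containment_in_holder(self):
        model = build_code_b(AssemblyConfig(code="B", n_nanosystems=500,
                                            seed=1))
        r_out = 40.6877
        for b in model.bodies:
            if b.shape != "spherical_shell":
                continue
            x, y, z = b.center
            assert math.hypot(x, y) <= 4250.0 - r_out + 1e-6
            assert abs(z) <= 500.0 - r_out + 1e-6


class TestLocate:
    def test_origin_of_code_a_is_sio2(self, code_a_model):
        medium, body = locate(code_a_model, (0.0, 0.0, 0.0))
        assert medium == "SiO2" and body == 0

    def test_shell_point_is_zno(self):
        model = build_code_b(AssemblyConfig(code="B", n_nanosystems=1,
                                            seed=0))
        c = np.asarray(model.bodies[0].center)
        p = c + np.array([40.35, 0.0, 0.0])
        medium, _ = locate(model, p)
        assert medium == "ZnO"

    def test_random_points_match_brute_force(self, code_a_model):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-60, 60, size=(400, 3))
        for p in pts:
            medium, _ = locate(code_a_model, p)
            # brute-force oracle over every body
            expected = "air"
            for b in code_a_model.bodies:
                if np.sum((p - np.asarray(b.center)) ** 2) < b.radii[0] ** 2:
                    expected = b.medium
                    break
            assert medium == expected

    def test_mc_volume_conservation(self, code_a_model):
        # uniform points + locate reproduce the analytic solid volume
        rng = np.random.default_rng(42)
        n = 200_000
        box = 45.5
        pts = rng.uniform(-box, box, size=(n, 3))
        host = sum(1 for p in pts
                   if locate(code_a_model, p)[0] == "SiO2")
        v_box = (2 * box) ** 3
        v_est = host / n * v_box
        v_true = sphere_volume(80.0)
        se = v_box * math.sqrt(host) / n
        assert abs(v_est - v_true) < 3 * se


class TestRaySegments:
    def test_diameter_chord_through_bare_sphere(self):
        model = build_code_a(AssemblyConfig(code="A", n_zno=0, seed=0))
        segs = ray_segments(model, (-450.0, 0.0, 0.0), (1.0, 0.0, 0.0))
        sio2 = [s for s in segs if s[1] == "SiO2"]
        assert len(sio2) == 1
        assert sio2[0][0] == pytest.approx(80.0, abs=1e-9)

    def test_lengths_sum_to_exit_distance(self, code_a_model):
        rng = np.random.default_rng(1)
        for _ in range(30):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            origin = rng.uniform(-30, 30, size=3)
            segs = ray_segments(code_a_model, origin, d)
            total = sum(s[0] for s in segs)
            # exit distance of the 500 nm world sphere
            b = float(origin @ d)
            c = float(origin @ origin) - 500.0**2
            t_exit = -b + math.sqrt(b * b - c)
            assert total == pytest.approx(t_exit, rel=1e-6)

    def test_coated_sphere_center_ray_pattern(self):
        model = build_code_b(AssemblyConfig(code="B", n_nanosystems=1,
                                            seed=0))
        c = np.asarray(model.bodies[0].center)
        origin = c - np.array([200.0, 0.0, 0.0])
        segs = ray_segments(model, origin, (1.0, 0.0, 0.0))
        media = [m for _, m in segs]
        assert media == ["air", "ZnO", "SiO2", "ZnO", "air"]
        zno = [ln for ln, m in segs if m == "ZnO"]
        assert zno[0] == pytest.approx(0.6877, abs=1e-3)
        assert zno[1] == pytest.approx(0.6877, abs=1e-3)

    def test_origin_outside_world_empty(self, code_a_model):
        assert ray_segments(code_a_model, (1e4, 0, 0), (1.0, 0, 0)) == []

    def test_non_unit_direction_rejected(self, code_a_model):
        with pytest.raises(ValueError):
            ray_segments(code_a_model, (0, 0, 0), (1.0, 1.0, 0.0))


def test_export_bodies_csv(tmp_path, code_a_model):
    import pandas as pd

    p = tmp_path / "bodies.csv"
    export_bodies_csv(code_a_model, p)
    df = pd.read_csv(p)
    assert len(df) == 216
    assert set(df.medium) == {"SiO2", "ZnO"}
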