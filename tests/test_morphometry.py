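"""Volumetry, surface area, classification and connection detection."""

import math

import numpy as np
import pytest

from vitrevol import (
    DEFAULT_VOXEL_EDGE,
    CavityModel,
    cavity_surface_area,
    cavity_volume,
    classify_cavities,
    compute_metrics,
    detect_connection,
    label_components,
    propagate_error,
    rescale_isotropic,
)
from vitrevol.morphometry import _marching_cubes_area


def make_model(mask, edge=DEFAULT_VOXEL_EDGE, class_map=None, connectivity=6):
    grid = mask.astype(np.int32)
    return CavityModel(
        label_grid=grid,
        voxel_edge=edge,
        class_map=class_map or {1: "PMP"},
        connectivity=connectivity,
    )


class TestRescaleIsotropic:
    def test_identity_when_already_isotropic(self):
        rng = np.random.default_rng(0)
        m = rng.random((20, 16, 12)) < 0.4
        e = DEFAULT_VOXEL_EDGE
        out = rescale_isotropic(m, (e, e, e), e)
        assert np.array_equal(out, m)

    def test_volume_preserved_on_anisotropic_grid(self):
        # sphere on the native anisotropic lattice (0.046875, 0.046875, ~0.046429)
        spacing = (12 / 256, 9 / 192, 2.6 / 56)
        shape = (96, 96, 56)
        c = np.array([48, 48, 28])
        x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
        r_mm = 0.9
        m = (
            ((x - c[0]) * spacing[0]) ** 2
            + ((y - c[1]) * spacing[1]) ** 2
            + ((z - c[2]) * spacing[2]) ** 2
        ) <= r_mm**2
        before = m.sum() * np.prod(spacing)
        out = rescale_isotropic(m, spacing)
        after = out.sum() * DEFAULT_VOXEL_EDGE**3
        assert after == pytest.approx(before, rel=0.02)

    def test_empty_in_empty_out(self):
        out = rescale_isotropic(np.zeros((10, 10, 10), bool), (0.1, 0.1, 0.05))
        assert not out.any()

    def test_bad_spacing_rejected(self):
        with pytest.raises(ValueError):
            rescale_isotropic(np.zeros((4, 4, 4), bool), (0.1, -1, 0.1))


class TestLabelComponents:
    def test_two_disjoint_spheres(self):
        m = np.zeros((40, 20, 20), bool)
        m[5:12, 5:12, 5:12] = True
        m[25:30, 5:10, 5:10] = True
        model = label_components(m)
        assert len(model.labels) == 2
        # deterministic order: biggest first
        assert (model.label_grid == 1).sum() > (model.label_grid == 2).sum()

    def test_face_bridge_merges_under_6_connectivity(self):
        m = np.zeros((20, 9, 9), bool)
        m[2:6, 2:7, 2:7] = True
        m[9:13, 2:7, 2:7] = True
        m[6:9, 4, 4] = True  # 1-voxel face-connected bridge
        assert len(label_components(m, connectivity=6).labels) == 1

    def test_corner_touch_separate_under_6_connectivity(self):
        m = np.zeros((6, 6, 6), bool)
        m[0:2, 0:2, 0:2] = True
        m[2:4, 2:4, 2:4] = True  # touches only at a corner
        assert len(label_components(m, connectivity=6).labels) == 2
        assert len(label_components(m, connectivity=26).labels) == 1

    def test_sizes_match_flood_fill_oracle(self):
        from test_postprocess import flood_fill_components

        rng = np.random.default_rng(5)
        m = rng.random((16, 16, 16)) < 0.25
        model = label_components(m, connectivity=26)
        sizes = sorted(
            int((model.label_grid == lab).sum()) for lab in model.labels
        )
        assert sizes == sorted(flood_fill_components(m, connectivity=26))


class TestVolumeAndArea:
    def test_single_voxel_calibration(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        v = cavity_volume(make_model(m), "PMP")
        assert v == pytest.approx(1.03e-4, rel=5e-3)  # printed calibration

    def test_digitized_sphere_volume(self, digitized_sphere):
        sph, r = digitized_sphere
        v = cavity_volume(make_model(sph), "PMP")
        expected = 4 / 3 * math.pi * r**3 * DEFAULT_VOXEL_EDGE**3
        assert v == pytest.approx(expected, rel=0.01)

    def test_single_voxel_octahedron_area(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        a = cavity_surface_area(make_model(m), "PMP")
        assert a == pytest.approx(math.sqrt(3) * DEFAULT_VOXEL_EDGE**2, rel=1e-6)

    def test_sphere_area_within_calibrated_tolerance(self, digitized_sphere):
        # binary marching cubes carries a ~+9% orientation-averaged bias
        sph, r = digitized_sphere
        a = cavity_surface_area(make_model(sph), "PMP")
        expected = 4 * math.pi * r**2 * DEFAULT_VOXEL_EDGE**2
        assert expected < a < 1.12 * expected

    def test_empty_structure_errors(self):
        m = np.zeros((3, 3, 3), bool)
        model = make_model(m, class_map={})
        with pytest.raises(ValueError, match="empty"):
            cavity_surface_area(model, "whole")

    def test_volume_linear_in_voxel_edge(self, digitized_sphere):
        sph, _ = digitized_sphere
        m1 = make_model(sph, edge=0.05)
        m2 = make_model(sph, edge=0.1)
        assert cavity_volume(m2, "PMP") == pytest.approx(8 * cavity_volume(m1, "PMP"))
        assert cavity_surface_area(m2, "PMP") == pytest.approx(
            4 * cavity_surface_area(m1, "PMP"), rel=1e-6
        )

    def test_translation_invariance(self):
        m = np.zeros((24, 24, 24), bool)
        m[4:10, 4:10, 4:10] = True
        shifted = np.roll(m, (6, 3, 5), axis=(0, 1, 2))
        a, b = make_model(m), make_model(shifted)
        assert cavity_volume(a, "PMP") == cavity_volume(b, "PMP")
        assert cavity_surface_area(a, "PMP") == pytest.approx(
            cavity_surface_area(b, "PMP"), rel=1e-9
        )

    def test_isoperimetric_tendency(self, digitized_sphere):
        # any same-volume non-spherical shape has at least the sphere's area
        sph, r = digitized_sphere
        cube_side = int(round((sph.sum()) ** (1 / 3)))
        cube = np.zeros_like(sph)
        cube[:cube_side, :cube_side, :cube_side] = True
        a_sph = cavity_surface_area(make_model(sph), "PMP")
        a_cube = cavity_surface_area(make_model(cube), "PMP")
        sphere_equiv = (36 * math.pi) ** (1 / 3) * (
            cube.sum() * DEFAULT_VOXEL_EDGE**3
        ) ** (2 / 3)
        assert a_cube > sphere_equiv
        assert a_sph > 4 * math.pi * (r * DEFAULT_VOXEL_EDGE) ** 2


class TestPropagateError:
    def test_sphere_half_voxel_rule(self, digitized_sphere):
        """dV = A*e/2 agrees with the half-voxel shell volume within the
        calibrated marching-cubes bias envelope."""
        sph, r = digitized_sphere
        model = make_model(sph)
        dv, da, eroded = propagate_error(model, "PMP")
        e = DEFAULT_VOXEL_EDGE
        shell = 4 / 3 * math.pi * ((r + 0.5) ** 3 - (r - 0.5) ** 3) / 2 * e**3
        assert not eroded
        assert dv == pytest.approx(shell, rel=0.12)
        v = cavity_volume(model, "PMP")
        # dV/V ~ 3e/(2r) modulated by the MC area bias
        assert dv / v == pytest.approx(1.5 / r, rel=0.12)
        assert da > 0

    def test_doubling_size_halves_relative_error(self):
        def rel_err(r):
            n = 2 * r + 5
            c = (n - 1) / 2
            x, y, z = np.ogrid[:n, :n, :n]
            sph = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= r * r
            model = make_model(sph)
            dv, _, _ = propagate_error(model, "PMP")
            return dv / cavity_volume(model, "PMP")

        assert rel_err(8) == pytest.approx(2 * rel_err(16), rel=0.1)

    def test_erosion_to_empty_flagged(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        dv, da, eroded = propagate_error(make_model(m), "PMP")
        assert eroded
        assert da > 0


class TestClassifyAndConnect:
    def test_disjoint_phantom_classes(self, noiseless_eye, noiseless_spec):
        vol, truth = noiseless_eye
        iso = rescale_isotropic(truth.fluid_mask, vol.spacing)
        model = label_components(iso)
        model = classify_cavities(model, vol.fovea_xy, vol.disc_xy)
        assert set(model.class_map.values()) == {"PMP", "CC"}
        assert model.connected_pmp_cc is False
        assert detect_connection(model) is False

    def test_connected_phantom_split_and_flagged(self, connected_eye):
        vol, truth = connected_eye
        iso = rescale_isotropic(truth.fluid_mask, vol.spacing)
        pre = label_components(iso)
        assert len(pre.labels) == 1  # canal joins everything
        model = classify_cavities(pre, vol.fovea_xy, vol.disc_xy)
        assert model.connected_pmp_cc is True
        assert detect_connection(model) is True
        # split partitions the merged component exactly
        pmp_v = cavity_volume(model, "PMP")
        cc_v = cavity_volume(model, "CC")
        assert pmp_v + cc_v == pytest.approx(
            pre.label_grid.astype(bool).sum() * model.voxel_volume
        )
        # the split puts the bigger share over the fovea
        assert pmp_v > cc_v

    def test_geodesic_split_matches_bfs_oracle(self):
        """Two cubes joined by a thin bridge: the split boundary falls at the
        midpoint of the bridge, as found by a two-source BFS."""
        from collections import deque

        m = np.zeros((40, 11, 11), bool)
        m[2:10, 1:10, 1:10] = True
        m[30:38, 1:10, 1:10] = True
        m[10:30, 5, 5] = True
        edge = 0.5
        model = CavityModel(
            label_grid=m.astype(np.int32), voxel_edge=edge, connectivity=6
        )
        # landmarks over the two cubes (en-face mm coordinates)
        fovea = ((5 + 0.5) * edge, (5 + 0.5) * edge)
        disc = ((34 + 0.5) * edge, (5 + 0.5) * edge)
        out = classify_cavities(model, disc_xy=disc, fovea_xy=fovea)

        # independent two-source BFS over the same 6-connected graph
        dist = {s: np.full(m.shape, -1, int) for s in "ab"}
        seeds = {"a": [(5, 5, z) for z in range(11) if m[5, 5, z]],
                 "b": [(34, 5, z) for z in range(11) if m[34, 5, z]]}
        for s in "ab":
            dq = deque(seeds[s])
            for p in seeds[s]:
                dist[s][p] = 0
            while dq:
                p = dq.popleft()
                for d in ((1,0,0),(-1,0,0),(0,1,0),(0,-1,0),(0,0,1),(0,0,-1)):
                    q = tuple(np.add(p, d))
                    if all(0 <= qi < si for qi, si in zip(q, m.shape)) and m[q] and dist[s][q] < 0:
                        dist[s][q] = dist[s][p] + 1
                        dq.append(q)
        expected_pmp = m & (dist["a"] <= dist["b"]) & (dist["a"] >= 0)
        got_pmp = out.structure_mask("PMP")
        assert np.array_equal(got_pmp, expected_pmp)

    def test_accessory_cavity_classified_other(self, noiseless_spec):
        from dataclasses import replace

        from vitrevol import Ellipsoid, generate_phantom

        spec = replace(
            noiseless_spec,
            accessory_cavities=[Ellipsoid((5.5, 7.0, 1.6), (0.5, 0.5, 0.3))],
        )
        vol, truth = generate_phantom(spec)
        iso = rescale_isotropic(truth.fluid_mask, vol.spacing)
        model = classify_cavities(label_components(iso), vol.fovea_xy, vol.disc_xy)
        assert sorted(model.class_map.values()) == ["CC", "PMP", "other"]

    def test_landmark_outside_field_rejected(self, noiseless_eye):
        vol, truth = noiseless_eye
        iso = rescale_isotropic(truth.fluid_mask, vol.spacing)
        model = label_components(iso)
        with pytest.raises(ValueError, match="outside"):
            classify_cavities(model, (25.0, 4.5), vol.disc_xy)

    def test_missing_structure_indeterminate(self):
        m = np.zeros((10, 10, 10), bool)
        m[2:5, 2:5, 2:5] = True
        model = make_model(m, class_map={1: "PMP"})
        assert detect_connection(model) is None


class TestComputeMetrics:
    def test_whole_equals_sum_of_parts(self, noiseless_eye):
        vol, truth = noiseless_eye
        iso = rescale_isotropic(truth.fluid_mask, vol.spacing)
        model = classify_cavities(label_components(iso), vol.fovea_xy, vol.disc_xy)
        metrics = compute_metrics(model)
        whole = metrics.get("whole").volume_mm3
        parts = metrics.get("PMP").volume_mm3 + metrics.get("CC").volume_mm3
        assert whole == pytest.approx(parts, abs=1e-12)
        assert metrics.connected_pmp_cc is False
        assert all(
            m.volume_mm3 >= 0 and m.area_mm2 >= 0 for m in metrics.structures.values()
        )
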