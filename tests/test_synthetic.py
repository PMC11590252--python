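"""Synthetic trace geometry, scene assembly and density simulation."""

import math

import numpy as np
import pytest

from cryosse.structures import HELIX, SHEET, ChainStructure, Residue
from cryosse.synthetic import (
    GEOMETRY, SceneSpec, assemble_scene, generate_dataset, make_coil_trace,
    make_helix_trace, make_sheet_trace, simulate_density,
)

from conftest import brute_force_labels


def fit_line_distances(points):
    """Distance of each point to the best-fit (total least squares) line."""
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c)
    axis = vt[0]
    rel = points - c
    proj = np.outer(rel @ axis, axis)
    return np.linalg.norm(rel - proj, axis=1)


class TestHelixTrace:
    def test_consecutive_ca_distance_is_ideal_chord(self):
        pts = make_helix_trace(12, seed_or_rng=5)
        r, rise = GEOMETRY["helix_radius"], GEOMETRY["helix_rise"]
        chord = math.sqrt(2 * r * r * (1 - math.cos(math.radians(100))) + rise ** 2)
        d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        np.testing.assert_allclose(d, chord, atol=1e-9)
        assert chord == pytest.approx(3.82, abs=0.01)

    def test_points_on_cylinder_of_radius_2p3(self):
        # 100°/residue means residues i and i+18 sit exactly 5 turns apart,
        # so their difference vector IS the (transformed) helix axis
        pts = make_helix_trace(22, seed_or_rng=3)
        axis = pts[18] - pts[0]
        axis /= np.linalg.norm(axis)
        on_axis = pts[0:18].mean(axis=0)  # full period: centroid on the axis
        rel = pts - on_axis
        dist = np.linalg.norm(rel - np.outer(rel @ axis, axis), axis=1)
        np.testing.assert_allclose(dist, GEOMETRY["helix_radius"], atol=1e-9)

    def test_seed_determinism_and_min_length(self):
        np.testing.assert_array_equal(
            make_helix_trace(8, seed_or_rng=9), make_helix_trace(8, seed_or_rng=9)
        )
        with pytest.raises(ValueError):
            make_helix_trace(3, seed_or_rng=0)


class TestSheetTrace:
    def test_adjacent_strand_pitch(self):
        pts, bounds = make_sheet_trace(3, 5, seed_or_rng=2)
        # distance between strand best-fit lines ~ inter-strand spacing
        s0 = pts[bounds[0][0]:bounds[0][1]].mean(axis=0)
        s1 = pts[bounds[1][0]:bounds[1][1]].mean(axis=0)
        assert np.linalg.norm(s1 - s0) == pytest.approx(
            GEOMETRY["strand_spacing"], abs=0.3
        )

    def test_within_strand_ca_distance(self):
        pts, bounds = make_sheet_trace(2, 6, seed_or_rng=4)
        rise, pleat = GEOMETRY["strand_rise"], GEOMETRY["strand_pleat"]
        expected = math.sqrt(rise ** 2 + (2 * pleat) ** 2)
        for a, b in bounds:
            d = np.linalg.norm(np.diff(pts[a:b], axis=0), axis=1)
            np.testing.assert_allclose(d, expected, atol=1e-9)
        assert expected == pytest.approx(3.76, abs=0.01)

    def test_total_residue_count_and_min_strands(self):
        pts, _ = make_sheet_trace(4, 5, seed_or_rng=0)
        assert pts.shape == (20, 3)
        with pytest.raises(ValueError):
            make_sheet_trace(1, 5, seed_or_rng=0)


class TestCoilTrace:
    def test_fixed_step_lengths(self):
        pts = make_coil_trace(25, seed_or_rng=6)
        d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        np.testing.assert_allclose(d, GEOMETRY["coil_step"], atol=1e-9)

    def test_self_avoidance_clearance(self):
        pts = make_coil_trace(30, seed_or_rng=1)
        n = len(pts)
        for i in range(n):
            for j in range(i + 2, n):  # non-consecutive pairs
                assert np.linalg.norm(pts[i] - pts[j]) >= GEOMETRY["coil_clearance"] - 1e-9

    def test_seed_determinism(self):
        np.testing.assert_array_equal(
            make_coil_trace(15, seed_or_rng=3), make_coil_trace(15, seed_or_rng=3)
        )


class TestSceneAssembly:
    def test_realized_fractions_near_targets(self):
        st = assemble_scene(SceneSpec(total_residues=120, seed=5))
        cls = st.classes_array()
        fh = (cls == HELIX).mean()
        fs = (cls == SHEET).mean()
        assert 0.32 <= fh <= 0.42
        assert 0.08 <= fs <= 0.18

    def test_pure_helix_scene(self):
        st = assemble_scene(SceneSpec(
            total_residues=12, target_fractions=(1.0, 0.0), n_helices=1, n_coils=0,
        ))
        assert set(st.classes_array()) == {HELIX}

    def test_determinism(self):
        spec = SceneSpec(total_residues=60, seed=17)
        a = assemble_scene(spec)
        b = assemble_scene(spec)
        np.testing.assert_array_equal(a.ca_array(), b.ca_array())
        assert list(a.classes_array()) == list(b.classes_array())

    def test_inter_element_clearance(self):
        st = assemble_scene(SceneSpec(total_residues=80, seed=2))
        from scipy.spatial import cKDTree
        by_chain = {}
        for r in st.residues:
            by_chain.setdefault(r.chain_id, []).append(r.ca_xyz)
        chains = [np.asarray(v) for v in by_chain.values()]
        for i in range(len(chains)):
            for j in range(i + 1, len(chains)):
                d = cKDTree(chains[i]).query(chains[j], k=1)[0].min()
                assert d >= GEOMETRY["element_clearance"] - 1e-9


class TestSimulateDensity:
    def test_point_source_kernel_values(self):
        st = ChainStructure([Residue("A", 1, [0.0, 0.0, 0.0], None, HELIX)])
        dm = simulate_density(st, resolution=8.0, spacing=1.0, margin=10.0)
        sigma = 8.0 / (2 * math.sqrt(2 * math.log(2)))
        c = np.rint(-np.array(dm.origin)).astype(int)
        assert dm.values[tuple(c)] == pytest.approx(1.0, abs=1e-6)
        d = 3
        expected = math.exp(-d * d / (2 * sigma * sigma))
        assert dm.values[c[0] + d, c[1], c[2]] == pytest.approx(expected, rel=1e-5)

    def test_distant_sources_additive(self):
        st = ChainStructure([
            Residue("A", 1, [0.0, 0.0, 0.0], None, HELIX),
            Residue("B", 1, [100.0, 0.0, 0.0], None, HELIX),
        ])
        dm = simulate_density(st, resolution=8.0, spacing=1.0, margin=8.0)
        single = simulate_density(
            ChainStructure(st.residues[:1]), resolution=8.0, spacing=1.0, margin=8.0
        )
        c = np.rint(-np.array(dm.origin)).astype(int)
        c1 = np.rint(-np.array(single.origin)).astype(int)
        assert dm.values[tuple(c)] == pytest.approx(single.values[tuple(c1)], abs=1e-6)

    def test_helix_renders_as_tube_not_beads(self):
        pts = make_helix_trace(20, seed_or_rng=0)
        st = ChainStructure([
            Residue("A", i + 1, p, None, HELIX) for i, p in enumerate(pts)
        ])
        dm = simulate_density(st, resolution=8.0, spacing=1.0, margin=10.0)
        peak = np.unravel_index(np.argmax(dm.values), dm.shape)
        peak_xyz = dm.voxel_center(peak)
        # the density maximum lies near the helix axis, not at a Cα
        c = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - c)
        axis = vt[0]
        rel = peak_xyz - c
        dist_axis = np.linalg.norm(rel - np.dot(rel, axis) * axis)
        assert dist_axis < 1.5

    def test_linearity_in_structure(self):
        a = ChainStructure([Residue("A", 1, [2.0, 3.0, 4.0], None, HELIX)])
        b = ChainStructure([Residue("B", 1, [8.0, 3.0, 4.0], None, SHEET)])
        both = ChainStructure(a.residues + b.residues)
        kw = dict(resolution=7.0, spacing=1.0, margin=9.0)
        da = simulate_density(a, **kw)
        db = simulate_density(b, **kw)
        dboth = simulate_density(both, **kw)
        # compare on the common grid point at each single source center
        ca = np.rint((np.array([2.0, 3.0, 4.0]) - dboth.origin)).astype(int)
        va = da.values[tuple(np.rint(np.array([2.0, 3.0, 4.0]) - da.origin).astype(int))]
        vb = db.values[tuple(np.rint(np.array([2.0, 3.0, 4.0]) - db.origin).astype(int))]
        assert dboth.values[tuple(ca)] == pytest.approx(va + vb, abs=1e-5)

    def test_resolution_spacing_precondition(self):
        st = ChainStructure([Residue("A", 1, [0, 0, 0], None, HELIX)])
        with pytest.raises(ValueError):
            simulate_density(st, resolution=1.5, spacing=1.0)


class TestGenerateDataset:
    def test_manifest_reproducible_and_consistent(self):
        spec = SceneSpec(total_residues=40, box_pad=8.0, noise=False)
        cases, manifest = generate_dataset(3, spec, seed=21)
        _, manifest2 = generate_dataset(3, spec, seed=21)
        assert manifest == manifest2
        for case, entry in zip(cases, manifest["cases"]):
            assert entry["counts"] == case.labels.class_counts()

    def test_sheet_fraction_below_helix_fraction(self):
        spec = SceneSpec(total_residues=100, box_pad=8.0, noise=False)
        cases, _ = generate_dataset(3, spec, seed=4)
        for case in cases:
            counts = case.labels.class_counts()
            assert counts.get(2, 0) < counts.get(1, 0)

    def test_labels_match_brute_force_oracle(self):
        spec = SceneSpec(total_residues=12, target_fractions=(0.5, 0.3),
                         box_pad=4.0, noise=False)
        cases, _ = generate_dataset(1, spec, seed=9)
        case = cases[0]
        if max(case.density.shape) <= 40:
            bf = brute_force_labels(case.structure, case.density)
            np.testing.assert_array_equal(case.labels.classes, bf)

    def test_invalid_case_count(self):
        with pytest.raises(ValueError):
            generate_dataset(0, SceneSpec(), seed=0)
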