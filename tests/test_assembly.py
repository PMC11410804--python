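"""Tile superposition, scoring, termination and unit-cell extraction."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from symlattice import assembly, fixtures, symmetry
from symlattice.assembly import (AssemblyTile, CannotConnectError,
                                 GapTooLargeError, P1InsufficientError,
                                 DegenerateCellError, align_axis_to_z,
                                 assemble_capsid_tile, assemble_p1,
                                 assemble_pair, bending_score,
                                 check_termination, clash_score,
                                 emit_lattice, expand_lattice, extract_cell,
                                 place_B_copies, propagate_A, QualityScores,
                                 read_lattice, score_tile)
from symlattice.io import ScoredOligomer


def _flat_tile(p4_complexes, p4_fixture, cfg):
    sc_a, sc_b = p4_complexes
    tile = AssemblyTile(central_A=align_axis_to_z(sc_a))
    place_B_copies(tile, sc_b, p4_fixture.shared_res, config=cfg)
    return tile


def _tilt_B_axes(tile, angle_deg):
    R = Rotation.from_euler("x", angle_deg, degrees=True).as_matrix()
    for placed in tile.B_copies:
        placed.raw_direction = R @ placed.raw_direction
    return tile


class TestAlignAxisToZ:
    def test_z_axis_is_fixed_point(self, p4_complexes):
        sc_a, _ = p4_complexes
        placed = align_axis_to_z(sc_a)
        assert np.allclose(placed.axis.direction, [0, 0, 1], atol=1e-9)
        assert np.allclose(placed.axis.anchor[:2], [0, 0], atol=1e-6)

    def test_tilted_axis_realigned_and_redetected(self, p4_fixture, cfg):
        model = p4_fixture.complex_A.model.copy()
        R = Rotation.from_euler("y", 90, degrees=True).as_matrix()
        model.transform(R, np.array([5.0, -3.0, 2.0]))
        olig = ScoredOligomer(model=model, score=p4_fixture.complex_A.score)
        sc = symmetry.detect(olig, "layer", cfg)
        placed = align_axis_to_z(sc)
        assert np.allclose(placed.axis.direction, [0, 0, 1], atol=1e-9)
        re = symmetry.detect(
            ScoredOligomer(model=placed.model, score=olig.score),
            "layer", cfg)
        assert re.axis.order_k == 4
        assert abs(re.axis.direction[2]) == pytest.approx(1.0, abs=1e-6)

    def test_chirality_preserved(self, p4_complexes):
        sc_a, _ = p4_complexes
        placed = align_axis_to_z(sc_a)
        assert np.linalg.det(placed.transform.rotation) == pytest.approx(1.0)


class TestPlacement:
    def test_p4_tile_has_four_tight_B_copies(self, p4_complexes, p4_fixture,
                                             cfg):
        tile = _flat_tile(p4_complexes, p4_fixture, cfg)
        assert len(tile.B_copies) == 4
        assert max(tile.overlap_rmsds) < 0.1

    def test_no_shared_residues_cannot_connect(self, p4_complexes, cfg):
        sc_a, sc_b = p4_complexes
        tile = AssemblyTile(central_A=align_axis_to_z(sc_a))
        with pytest.raises(CannotConnectError):
            place_B_copies(tile, sc_b, [], config=cfg)

    def test_deformed_B_raises_gap_too_large(self, p4_complexes, p4_fixture,
                                             cfg):
        sc_a, _ = p4_complexes
        noisy = fixtures.make_lattice_pair("p4", seed=7)
        rng = np.random.default_rng(0)
        model = noisy.complexes_B[0].model
        for ch in model.chains:
            ch.coords = ch.coords + rng.normal(scale=4.0,
                                               size=ch.coords.shape)
        sc_b = symmetry.detect(noisy.complexes_B[0], "layer", cfg)
        assert not isinstance(sc_b, symmetry.AxisRejection)
        tile = AssemblyTile(central_A=align_axis_to_z(sc_a))
        with pytest.raises(GapTooLargeError):
            place_B_copies(tile, sc_b, p4_fixture.shared_res, config=cfg)

    def test_propagation_places_lattice_neighbours(self, p4_complexes,
                                                   p4_fixture, cfg):
        tile = _flat_tile(p4_complexes, p4_fixture, cfg)
        propagate_A(tile, p4_fixture.shared_res, config=cfg)
        anchors = np.array([p.axis.anchor[:2] for p in tile.peripheral_A])
        lengths = np.linalg.norm(anchors, axis=1)
        # four nearest neighbours at a = 100, four diagonal at a*sqrt(2)
        assert np.isclose(lengths, 100.0, atol=0.5).sum() == 4
        for p in tile.peripheral_A:
            assert p.axis.order_k == tile.central_A.axis.order_k

    def test_p6_propagation_gives_six_neighbours(self, cfg):
        fix = fixtures.make_lattice_pair("p6", seed=5)
        sc_a = symmetry.detect(fix.complex_A, "layer", cfg)
        sc_b = symmetry.detect(fix.complexes_B[0], "layer", cfg)
        res = assemble_pair(sc_a, sc_b, fix.shared_res, config=cfg)
        anchors = np.array([p.axis.anchor[:2]
                            for p in res.tile.peripheral_A])
        lengths = np.linalg.norm(anchors, axis=1)
        assert np.isclose(lengths, 170.0, atol=0.5).sum() == 6


class TestScores:
    def test_flat_tile_bends_zero(self, p4_complexes, p4_fixture, cfg):
        tile = _flat_tile(p4_complexes, p4_fixture, cfg)
        assert bending_score(tile) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("angle,expected", [(90.0, 1.0), (45.0, 0.5)])
    def test_uniform_tilt_maps_linearly(self, p4_complexes, p4_fixture, cfg,
                                        angle, expected):
        tile = _tilt_B_axes(_flat_tile(p4_complexes, p4_fixture, cfg), angle)
        assert bending_score(tile) == pytest.approx(expected, abs=1e-9)

    def test_rms_of_mixed_tilts(self, p4_complexes, p4_fixture, cfg):
        tile = _flat_tile(p4_complexes, p4_fixture, cfg)
        for i, placed in enumerate(tile.B_copies):
            ang = [0.0, 30.0, 60.0, 90.0][i]
            R = Rotation.from_euler("x", ang, degrees=True).as_matrix()
            placed.raw_direction = R @ placed.raw_direction
        phis = np.radians([0, 30, 60, 90])
        expected = 2 / math.pi * math.sqrt(np.mean(phis ** 2))
        assert bending_score(tile) == pytest.approx(expected, abs=1e-9)

    def test_clash_score_zero_on_clean_tile(self, p4_complexes, p4_fixture,
                                            cfg):
        tile = _flat_tile(p4_complexes, p4_fixture, cfg)
        assert clash_score(tile, cfg) == 0.0

    def test_clash_score_is_count_over_residues(self, p4_complexes,
                                                p4_fixture, cfg):
        from symlattice.filters import clash_pairs
        tile = _flat_tile(p4_complexes, p4_fixture, cfg)
        # shift one B copy to overlap the centre
        tile.B_copies[0].model.transform(
            np.eye(3), -tile.B_copies[0].axis.anchor * 0.9)
        merged = tile.merged_model()
        expected = len(clash_pairs(merged, cfg)) / merged.n_res
        assert expected > 0
        assert clash_score(tile, cfg) == pytest.approx(expected)

    def test_quality_is_sum(self):
        q = QualityScores(score_clash=0.05, score_bend=0.5)
        assert q.score_quality == pytest.approx(0.55)

    def test_planted_pair_outranks_perturbed_decoys(self, cfg):
        """The quality score prefers the planted tile over tilted or
        deformed variants in every seed."""
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            fix = fixtures.make_lattice_pair("p4", seed=seed,
                                             noise_sigma=0.3)
            sc_a = symmetry.detect(fix.complex_A, "layer", cfg)
            sc_b = symmetry.detect(fix.complexes_B[0], "layer", cfg)
            res = assemble_pair(sc_a, sc_b, fix.shared_res, config=cfg)
            planted = res.scores.score_quality
            decoys = []
            for angle in (25.0, 50.0):
                t2 = _tilt_B_axes(
                    assemble_pair(sc_a, sc_b, fix.shared_res,
                                  config=cfg).tile, angle)
                decoys.append(score_tile(t2, cfg).score_quality)
            t3 = assemble_pair(sc_a, sc_b, fix.shared_res, config=cfg).tile
            rng = np.random.default_rng(seed)
            for placed in t3.B_copies:
                for ch in placed.model.chains:
                    ch.coords = ch.coords + rng.normal(
                        scale=1.5, size=ch.coords.shape)
            decoys.append(score_tile(t3, cfg).score_quality)
            if planted < min(decoys):
                wins += 1
        assert wins >= n_seeds - 1


class TestTermination:
    def test_flat_tile_is_ok(self, p4_complexes, p4_fixture, cfg):
        sc_a, sc_b = p4_complexes
        res = assemble_pair(sc_a, sc_b, p4_fixture.shared_res, config=cfg)
        assert res.termination == []

    def test_tilt_gate_strictly_above_45(self, p4_complexes, p4_fixture,
                                         cfg):
        tile = _tilt_B_axes(_flat_tile(p4_complexes, p4_fixture, cfg), 50.0)
        assert "tilt" in check_termination(tile, None, cfg)
        tile2 = _tilt_B_axes(_flat_tile(p4_complexes, p4_fixture, cfg), 45.0)
        assert "tilt" not in check_termination(tile2, None, cfg)

    def test_deformed_monomers_are_not_rigid(self, p4_fixture, cfg):
        model = p4_fixture.complex_A.model.copy()
        rng = np.random.default_rng(3)
        for ch in model.chains[:2]:
            ch.coords = ch.coords + rng.normal(scale=4.0,
                                               size=ch.coords.shape)
        olig = ScoredOligomer(model=model, score=p4_fixture.complex_A.score)
        sc = symmetry.detect(olig, "layer", cfg)
        assert not isinstance(sc, symmetry.AxisRejection)
        tile = AssemblyTile(central_A=align_axis_to_z(sc))
        assert "not_rigid" in check_termination(tile, None, cfg)


class TestExtractCell:
    def test_planted_p4_cell_exact(self, p4_complexes, p4_fixture, cfg):
        sc_a, sc_b = p4_complexes
        res = assemble_pair(sc_a, sc_b, p4_fixture.shared_res, config=cfg)
        assert res.cell.group == "p4"
        assert res.cell.a == pytest.approx(100.0, abs=0.01)
        assert res.cell.b == pytest.approx(100.0, abs=0.01)
        assert res.cell.gamma == 90.0

    def test_planted_p6_cell_exact(self, cfg):
        fix = fixtures.make_lattice_pair("p6", a=170.0, seed=5)
        sc_a = symmetry.detect(fix.complex_A, "layer", cfg)
        sc_b = symmetry.detect(fix.complexes_B[0], "layer", cfg)
        res = assemble_pair(sc_a, sc_b, fix.shared_res, config=cfg)
        assert res.cell.group == "p6"
        assert res.cell.a == pytest.approx(170.0, abs=0.02)
        assert res.cell.gamma == 120.0

    @pytest.mark.parametrize("seed", range(20))
    def test_noisy_p4_within_one_percent(self, seed, cfg):
        fix = fixtures.make_lattice_pair("p4", seed=seed, noise_sigma=0.3)
        sc_a = symmetry.detect(fix.complex_A, "layer", cfg)
        sc_b = symmetry.detect(fix.complexes_B[0], "layer", cfg)
        res = assemble_pair(sc_a, sc_b, fix.shared_res, config=cfg)
        assert abs(res.cell.a - 100.0) / 100.0 < 0.01

    def test_single_direction_raises_collinear(self, p4_complexes,
                                               p4_fixture, cfg):
        tile = _flat_tile(p4_complexes, p4_fixture, cfg)
        propagate_A(tile, p4_fixture.shared_res, config=cfg)
        along_x = [p for p in tile.peripheral_A
                   if abs(p.axis.anchor[1]) < 1.0]
        tile.peripheral_A = along_x
        with pytest.raises(assembly.CollinearVectorsError):
            extract_cell(tile, group="p4", config=cfg)


class TestEmitLattice:
    def test_round_trip_cell_and_operators(self, p4_complexes, p4_fixture,
                                           cfg, tmp_path):
        sc_a, sc_b = p4_complexes
        res = assemble_pair(sc_a, sc_b, p4_fixture.shared_res, config=cfg)
        path = emit_lattice(res.lattice, tmp_path / "cell.cif")
        back = read_lattice(path)
        assert back.cell.group == "p4"
        assert back.cell.a == pytest.approx(res.cell.a, abs=1e-3)
        assert back.cell.gamma == pytest.approx(res.cell.gamma, abs=1e-3)
        assert back.symops == ["x,y,z", "-y,x,z", "-x,-y,z", "y,-x,z"]

    def test_operators_regenerate_the_tile(self, p4_complexes, p4_fixture,
                                           cfg, tmp_path):
        sc_a, sc_b = p4_complexes
        res = assemble_pair(sc_a, sc_b, p4_fixture.shared_res, config=cfg)
        back = read_lattice(emit_lattice(res.lattice, tmp_path / "c.cif"))
        expanded = expand_lattice(back, n_cells=1)
        exp_centroids = [np.nanmean(c.ca_coords(), axis=0)
                         for c in expanded.chains]
        for ch in res.tile.merged_model().chains:
            cen = np.nanmean(ch.ca_coords(), axis=0)
            dmin = min(np.linalg.norm(cen - e) for e in exp_centroids)
            assert dmin < 2e-2

    def test_p1_cell_has_identity_operator_only(self, cfg, tmp_path):
        fix = fixtures.make_lattice_pair("p1", seed=3)
        lattice = assemble_p1(fix.monomer, fix.heterodimers, cfg)
        back = read_lattice(emit_lattice(lattice, tmp_path / "p1.cif"))
        assert back.symops == ["x,y,z"]


class TestP1Assembly:
    def test_oblique_cell_recovered_within_one_percent(self, cfg):
        fix = fixtures.make_lattice_pair("p1", a=73.0, b=89.0, gamma=105.0,
                                         seed=3)
        lattice = assemble_p1(fix.monomer, fix.heterodimers, cfg)
        assert lattice.cell.a == pytest.approx(73.0, rel=0.01)
        assert lattice.cell.b == pytest.approx(89.0, rel=0.01)
        assert lattice.cell.gamma == pytest.approx(105.0, abs=1.0)

    def test_one_interaction_is_insufficient(self, cfg):
        fix = fixtures.make_lattice_pair("p1", seed=3)
        with pytest.raises(P1InsufficientError):
            assemble_p1(fix.monomer, fix.heterodimers[:1], cfg)

    def test_parallel_vectors_are_degenerate(self, cfg):
        fix = fixtures.make_lattice_pair("p1", seed=3)
        model1, score, interval = fix.heterodimers[0]
        twin = model1.copy()
        twin.name = "het_twin"
        twin.chains[1].coords = twin.chains[1].coords + np.array([73.0, 0, 0])
        with pytest.raises(DegenerateCellError):
            assemble_p1(fix.monomer,
                        [fix.heterodimers[0], (twin, score, interval)], cfg)


class TestCapsidTile:
    def test_icosahedral_inter_axis_angle(self, cfg):
        pent, tri, truth = fixtures.make_capsid_patch(seed=0)
        sc5 = symmetry.detect(pent, "capsid", cfg)
        sc3 = symmetry.detect(tri, "capsid", cfg)
        shared = list(range(1, truth.extras["n_res"] + 1))
        tile = assemble_capsid_tile(sc5, sc3, shared, cfg)
        expected = truth.extras["inter_axis_angle_deg"]
        assert expected == pytest.approx(
            math.degrees(math.acos(
                math.sqrt((5 + 2 * math.sqrt(5)) / 15))), abs=1e-6)
        for tilt in tile.tilt_angles():
            assert tilt == pytest.approx(expected, abs=0.5)

    def test_flat_input_in_capsid_mode_has_no_tilt(self, p4_fixture, cfg):
        sc_a = symmetry.detect(p4_fixture.complex_A, "capsid", cfg)
        sc_b = symmetry.detect(p4_fixture.complexes_B[0], "capsid", cfg)
        tile = assemble_capsid_tile(sc_a, sc_b, p4_fixture.shared_res, cfg)
        assert max(tile.tilt_angles()) < 0.01
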