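"""Interface distograms, correlation graph and Louvain axis clusters."""

import random

import numpy as np
import pytest

from symlattice import clustering, fixtures, symmetry
from symlattice.clustering import (AxisCluster, InterfaceMatrix,
                                   NoInterfaceError, OneAxisOnlyError,
                                   build_graph, interface_matrix,
                                   louvain_partition, matrix_correlation,
                                   rank_pairs)
from symlattice.io import ScoredOligomer, ScoreEntry


def _crop(olig, interval, name, score):
    model = olig.model.copy()
    model.name = name
    lo, hi = interval
    model.chains = [c.subset(range(lo, hi + 1)) for c in model.chains]
    return ScoredOligomer(model=model, score=ScoreEntry(combined=score))


@pytest.fixture(scope="module")
def crop_complexes(cfg):
    """Two planted interfaces (A- and B-type), four subchain crops each."""
    fix = fixtures.make_lattice_pair("p4", seed=2)
    n = fix.monomer.n_res
    complexes, truth = [], {}
    for tag, base in [("A", fix.complex_A), ("B", fix.complexes_B[0])]:
        for i, iv in enumerate([(1, n), (5, n), (1, n - 4), (3, n - 2)]):
            sc = symmetry.detect(_crop(base, iv, f"{tag}_crop{i}",
                                       0.9 - 0.05 * i), "layer", cfg)
            assert not isinstance(sc, symmetry.AxisRejection)
            complexes.append(sc)
            truth[sc.name] = tag
    return complexes, truth


class TestInterfaceMatrix:
    def test_touching_dimer_has_close_entries(self, p4_complexes, cfg):
        sc_a, _ = p4_complexes
        mat = interface_matrix(sc_a, cfg)
        assert mat.values.min() < 5.0
        assert mat.values.max() <= cfg.d_cap

    def test_crops_agree_on_shared_indices(self, crop_complexes, cfg):
        complexes, _ = crop_complexes
        full = interface_matrix(complexes[0], cfg)
        cropped = interface_matrix(complexes[1], cfg)
        shared = np.intersect1d(full.res_ids, cropped.res_ids)
        i1 = np.searchsorted(full.res_ids, shared)
        i2 = np.searchsorted(cropped.res_ids, shared)
        assert np.allclose(full.values[np.ix_(i1, i1)],
                           cropped.values[np.ix_(i2, i2)], atol=1e-6)

    def test_entries_match_brute_force_min_distance(self, cfg):
        mono = fixtures.make_monomer(1, 30, seed=6)
        olig, _ = fixtures.make_oligomer(mono, k=2, m=2, seed=0)
        sc = symmetry.detect(olig, "layer", cfg)
        mat = interface_matrix(sc, cfg)
        ref = olig.model.get_chain(sc.chain_order[0])
        succ = olig.model.get_chain(sc.chain_order[1])
        for i in range(0, ref.n_res, 7):
            for j in range(0, succ.n_res, 7):
                a = ref.coords[(ref.atom_res == i) & ref.heavy_mask]
                b = succ.coords[(succ.atom_res == j) & succ.heavy_mask]
                d = min(cfg.d_cap,
                        float(np.linalg.norm(a[:, None] - b[None], axis=2).min()))
                assert mat.values[i, j] == pytest.approx(d, abs=1e-9)

    def test_distant_chains_raise_no_interface(self, cfg):
        mono = fixtures.make_monomer(1, 30, seed=6)
        olig, _ = fixtures.make_oligomer(mono, k=2, m=2, radius=80.0, seed=0)
        sc = symmetry.detect(olig, "layer", cfg)
        with pytest.raises(NoInterfaceError):
            interface_matrix(sc, cfg)


class TestMatrixCorrelation:
    def _mat(self, contacts, n=30):
        values = np.full((n, n), 10.0)
        for i, j in contacts:
            values[i, j] = 3.0
        return InterfaceMatrix(values=values,
                               res_ids=np.arange(1, n + 1), d_cap=10.0)

    def test_identical_matrices_correlate_to_one(self):
        m = self._mat([(0, 1), (5, 6), (9, 2)])
        assert matrix_correlation(m, m) == pytest.approx(1.0)

    def test_disjoint_interfaces_do_not_correlate(self):
        m1 = self._mat([(i, i) for i in range(6)])
        m2 = self._mat([(i, i + 10) for i in range(6)])
        assert matrix_correlation(m1, m2) <= 0.0

    def test_matches_hand_computed_pearson(self):
        m1 = self._mat([(0, 0), (1, 1), (2, 2)])
        m2 = self._mat([(0, 0), (1, 1), (4, 4)])
        v1 = m1.contacts(5.0).ravel().astype(float)
        v2 = m2.contacts(5.0).ravel().astype(float)
        expected = float(np.corrcoef(v1, v2)[0, 1])
        assert matrix_correlation(m1, m2) == pytest.approx(expected)

    def test_zero_variance_warns_zero(self):
        m1 = self._mat([])
        m2 = self._mat([(0, 0)])
        with pytest.warns(UserWarning):
            assert matrix_correlation(m1, m2) == 0.0

    def test_too_few_shared_positions(self):
        m1 = self._mat([(0, 0)], n=10)
        m2 = self._mat([(0, 0)], n=10)
        with pytest.raises(ValueError):
            matrix_correlation(m1, m2)


class TestGraphAndLouvain:
    def test_single_node_no_edges(self, p4_complexes, cfg):
        sc_a, _ = p4_complexes
        g = build_graph([sc_a], cfg)
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0
        clusters = louvain_partition(g)
        assert len(clusters) == 1 and clusters[0].members == [sc_a]

    def test_planted_interfaces_recovered_with_purity_one(self,
                                                          crop_complexes,
                                                          cfg):
        complexes, truth = crop_complexes
        g = build_graph(complexes, cfg)
        clusters = louvain_partition(g, seed=cfg.seed)
        assert len(clusters) == 2
        for cl in clusters:
            assert len({truth[m.name] for m in cl.members}) == 1

    def test_permutation_invariant(self, crop_complexes, cfg):
        complexes, _ = crop_complexes
        shuffled = list(complexes)
        random.Random(99).shuffle(shuffled)
        c1 = louvain_partition(build_graph(complexes, cfg), seed=cfg.seed)
        c2 = louvain_partition(build_graph(shuffled, cfg), seed=cfg.seed)
        names1 = sorted(tuple(m.name for m in cl.members) for cl in c1)
        names2 = sorted(tuple(m.name for m in cl.members) for cl in c2)
        assert names1 == names2

    def test_partial_representation_votes_for_higher_order(self, cfg):
        """A 60-degree trimer and a hexamer on one interface cluster
        together and the consensus order is 6."""
        fix = fixtures.make_lattice_pair("p6", seed=4)
        hexamer = symmetry.detect(fix.complex_A, "layer", cfg)
        trimer_model = fix.complex_A.model.copy()
        trimer_model.name = "partial_trimer"
        trimer_model.chains = trimer_model.chains[:3]
        trimer = symmetry.detect(
            ScoredOligomer(model=trimer_model,
                           score=ScoreEntry(combined=0.7)), "layer", cfg)
        assert trimer.axis.order_k == 6 and trimer.axis.filled == 0.5
        clusters = louvain_partition(
            build_graph([hexamer, trimer], cfg), seed=cfg.seed)
        assert len(clusters) == 1
        assert clusters[0].consensus_order == 6
        assert clusters[0].support == [3, 6]


def _dummy_complex(name, order, score):
    mono = fixtures.make_monomer(1, 30, seed=0)
    olig, _ = fixtures.make_oligomer(mono, k=order, m=2, seed=0)
    olig.model.name = name
    olig.score = ScoreEntry(combined=score)
    sc = symmetry.detect(olig, "layer")
    assert not isinstance(sc, symmetry.AxisRejection)
    return sc


class TestRankPairs:
    def _cluster(self, *members):
        rep = max(members, key=lambda sc: sc.score)
        return AxisCluster(members=list(members),
                           consensus_order=rep.axis.order_k,
                           representative=rep)

    def test_pairs_ordered_by_weaker_representative(self):
        a = self._cluster(_dummy_complex("a", 4, 0.9))
        b = self._cluster(_dummy_complex("b", 4, 0.8))
        c = self._cluster(_dummy_complex("c", 4, 0.5))
        pairs = rank_pairs([a, b, c])
        firsts = [(p[2].name, p[3].name) for p in pairs[:3]]
        assert firsts[0] == ("a", "b")       # min 0.8 beats min 0.5

    def test_single_cluster_is_one_axis_only(self):
        a = self._cluster(_dummy_complex("a", 4, 0.9))
        with pytest.raises(OneAxisOnlyError):
            rank_pairs([a])

    def test_equal_scores_break_by_higher_order(self):
        a = self._cluster(_dummy_complex("a", 6, 0.8))
        b = self._cluster(_dummy_complex("b", 6, 0.8))
        c = self._cluster(_dummy_complex("c", 2, 0.8))
        pairs = rank_pairs([a, b, c])
        assert {pairs[0][2].name, pairs[0][3].name} == {"a", "b"}

    def test_fallback_members_appended(self):
        a = self._cluster(_dummy_complex("a1", 4, 0.9),
                          _dummy_complex("a2", 4, 0.6))
        b = self._cluster(_dummy_complex("b1", 4, 0.8))
        pairs = rank_pairs([a, b])
        assert len(pairs) == 2
        assert (pairs[0][2].name, pairs[0][3].name) == ("a1", "b1")
        assert (pairs[1][2].name, pairs[1][3].name) == ("a2", "b1")
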