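"""Domain segmentation and the subchain truncation scheme."""

import numpy as np
import pytest

from symlattice import fixtures
from symlattice.domains import (DomainPartition, crop_linkers,
                                identify_domains, initial_subsections,
                                make_subchains, merge_to_domains,
                                p1_single_domains)
from symlattice.geometry import contact_count
from symlattice.sse import assign_sse
from symlattice.structure import StructureModel


def _model_of(residues):
    m = StructureModel(name="m")
    m.add_chain(fixtures._chain_from_residues("A", residues))
    return assign_sse(m)


class TestInitialSubsections:
    def test_two_separated_bundles_give_two_intervals(self, monomer2, cfg):
        subs = initial_subsections(monomer2, cfg)
        assert len(subs) == 2

    def test_single_bundle_gives_one_interval(self, cfg):
        m = _model_of(fixtures.helical_bundle(44))
        assert len(initial_subsections(m, cfg)) == 1

    def test_all_coil_chain_warns_single_interval(self, cfg):
        m = _model_of(fixtures.extended_strand(30))
        with pytest.warns(UserWarning):
            subs = initial_subsections(m, cfg)
        assert subs == [(1, 30)]

    def test_linked_helices_obey_contact_oracle(self, cfg):
        """Consecutive SSE segments merge iff they share >= k_link contacts."""
        m = _model_of(fixtures.helical_bundle(44))
        from symlattice.domains import _sse_segments
        segs = _sse_segments(m.chains[0])
        assert len(segs) >= 2
        for s1, s2 in zip(segs[:-1], segs[1:]):
            n = contact_count(m, [("A", r) for r in range(s1[0], s1[1] + 1)],
                              [("A", r) for r in range(s2[0], s2[1] + 1)],
                              cfg.contact_cutoff)
            assert n >= cfg.k_link   # hence one interval


class TestMerging:
    def test_zero_contact_blobs_stay_apart(self, monomer2, cfg):
        part = merge_to_domains(monomer2, [(1, 50), (51, 102)], cfg)
        assert len(part) == 2

    def test_artificially_split_blob_remerges(self, cfg):
        m = _model_of(fixtures.helical_bundle(44))
        part = merge_to_domains(m, [(1, 22), (23, 44)], cfg)
        assert part.intervals == [(1, 44)]

    def test_touching_pair_merges_isolated_stays(self, cfg):
        """Three blobs: A-B touching -> one domain, C isolated -> its own."""
        bundle = fixtures.helical_bundle(44)
        coords = fixtures._residue_coords(bundle)
        offset = np.array([60.0, 0, 0])
        t = fixtures._tune_approach(coords + offset, coords, offset)
        sep = 60.0 - t   # separation at which the pair just touches
        b2 = fixtures._transform_residues(bundle, np.eye(3),
                                          np.array([sep, 0, 0]))
        b3 = fixtures._transform_residues(bundle, np.eye(3),
                                          np.array([sep + 80.0, 0, 0]))
        m = _model_of(bundle + b2 + b3)
        part = merge_to_domains(m, [(1, 44), (45, 88), (89, 132)], cfg)
        assert part.intervals == [(1, 88), (89, 132)]

    def test_idempotent(self, monomer2, cfg):
        part = identify_domains(monomer2, cfg)
        again = merge_to_domains(monomer2, part.intervals, cfg)
        assert again.intervals == part.intervals

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_blob_count_recovered(self, k, cfg):
        m = assign_sse(fixtures.make_monomer(k, 44, seed=k))
        part = identify_domains(m, cfg)
        assert len(part) == k

    def test_partition_covers_chain_without_overlap(self, cfg):
        m = assign_sse(fixtures.make_monomer(3, 44, seed=9))
        part = identify_domains(m, cfg)
        covered = set()
        for s, e in part.intervals:
            span = set(range(s, e + 1))
            assert not covered & span
            covered |= span
        assert len(covered) >= 0.9 * m.chains[0].n_res


class TestCropLinkers:
    def test_zero_cross_contact_cut_is_unique_minimum(self, cfg):
        """A coil chain with one spatial break: the cut lands exactly
        at the break, where zero contacts cross the boundary."""
        from symlattice.structure import AtomRecord, Chain
        ch = Chain("A")
        for i in range(20):
            x = 1.6 * i + (10.0 if i >= 10 else 0.0)
            ch.add_residue(i + 1, "ALA", [AtomRecord("CA", "C", [x, 0, 0])])
        m = assign_sse(StructureModel([ch]))
        part = crop_linkers(m, DomainPartition([(1, 5), (6, 20)]), cfg)
        assert part.intervals == [(1, 10), (11, 20)]

    def test_cut_is_argmin_over_linker_scan(self, monomer2, cfg):
        """Exhaustive scan oracle with the tie rule (fewest crossing
        contacts, then nearest the linker midpoint)."""
        part = identify_domains(monomer2, cfg)
        assert len(part) == 2
        cut = part.intervals[0][1]
        chain = monomer2.chains[0]
        sse = dict(zip(chain.res_ids, chain.sse))
        lo, hi = 1, chain.n_res
        coil = [r for r in chain.res_ids if sse[r] == "C"]
        run = [r for r in coil if 40 <= r <= 60]   # linker region

        def cross(c):
            return contact_count(
                monomer2, [("A", r) for r in range(lo, c + 1)],
                [("A", r) for r in range(c + 1, hi + 1)], cfg.contact_cutoff)

        mid = 0.5 * (run[0] + run[-1])
        oracle = min(run, key=lambda c: (cross(c), abs(c - mid), c))
        assert cross(cut) == cross(oracle)

    def test_cut_lands_inside_true_linker(self, monomer2, cfg):
        part = identify_domains(monomer2, cfg)
        (s1, e1), (s2, _) = fixtures.monomer_domain_intervals(2, 44)
        cut = part.intervals[0][1]
        assert e1 <= cut < s2

    def test_single_domain_partition_unchanged(self, monomer2, cfg):
        part = DomainPartition([(1, 102)])
        assert crop_linkers(monomer2, part, cfg).intervals == [(1, 102)]


class TestSubchainScheme:
    def test_six_domain_protein_yields_published_five(self, cfg):
        part = DomainPartition([(i * 100 + 1, (i + 1) * 100)
                                for i in range(6)])
        specs = make_subchains(part, 600, cfg)
        by_id = {s.id: s.interval for s in specs}
        assert len(specs) == 5
        assert by_id["full"] == (1, 600)
        assert by_id["no_nterm"] == (101, 600)
        assert by_id["no_cterm"] == (1, 500)
        assert by_id["first_third"] == (1, 200)
        assert by_id["last_third"] == (401, 600)

    def test_three_domains_first_third_is_first_domain(self, cfg):
        part = DomainPartition([(1, 150), (151, 300), (301, 450)])
        specs = make_subchains(part, 450, cfg)
        by_id = {s.id: s.interval for s in specs}
        assert by_id["first_third"] == (1, 150)
        assert by_id["last_third"] == (301, 450)

    def test_single_domain_flagged_short_list(self, cfg):
        part = DomainPartition([(1, 200)])
        with pytest.warns(UserWarning):
            specs = make_subchains(part, 200, cfg)
        assert len(specs) == 1
        assert specs[0].id == "full"

    def test_short_intervals_clamped_to_min_len(self, cfg):
        part = DomainPartition([(1, 50), (51, 100), (101, 400)])
        specs = make_subchains(part, 400, cfg)
        assert all(s.length >= cfg.subchain_min_len for s in specs)

    def test_duplicates_collapsed_with_warning(self, cfg):
        # two domains: no_nterm == last_third and no_cterm == first_third
        part = DomainPartition([(1, 200), (201, 400)])
        with pytest.warns(UserWarning):
            specs = make_subchains(part, 400, cfg)
        intervals = [s.interval for s in specs]
        assert len(intervals) == len(set(intervals))


class TestP1SingleDomains:
    def test_one_spec_per_domain_sorted(self):
        part = DomainPartition([(1, 100), (101, 220), (221, 300), (301, 400)])
        specs = p1_single_domains(part)
        assert len(specs) == 4
        assert [s.interval for s in specs] == part.intervals
        assert [s.id for s in specs] == [f"single_domain:{k}"
                                         for k in range(4)]

    def test_single_domain_directs_to_standard_mode(self):
        with pytest.raises(ValueError):
            p1_single_domains(DomainPartition([(1, 100)]))
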