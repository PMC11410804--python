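"""Interface-similarity clustering of symmetry complexes.

Two symmetry complexes describe the same rotational axis of the final
lattice when their binding interfaces agree, regardless of how the
underlying subchains were cropped.  Each complex is characterised by an
interface distogram -- the matrix of minimum heavy-atom distances
between a reference monomer and its +1 neighbour around the axis,
indexed in full-length residue numbering and capped at `d_cap`.  Edge
weights of the complex graph are Pearson correlations of the binarised
(contact / no contact) distograms over shared index ranges, and the
graph is partitioned with the Louvain method (networkx implementation;
seeded, hence deterministic).  Each community is a candidate rotational
axis.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .config import PipelineConfig
from .geometry import min_residue_distances
from .symmetry import SymmetryComplex


class NoInterfaceError(ValueError):
    pass


class OneAxisOnlyError(RuntimeError):
    """Fewer than two axis clusters: a 2D layer cannot be spanned."""


@dataclass
class InterfaceMatrix:
    """Distogram between the reference monomer and its +1 neighbour."""

    values: np.ndarray            # (n, n) min distances, capped at d_cap
    res_ids: np.ndarray           # full-length residue numbers (both axes)
    d_cap: float

    def contacts(self, cutoff: float) -> np.ndarray:
        return self.values < cutoff


def interface_matrix(complex_: SymmetryComplex,
                     config: PipelineConfig | None = None) -> InterfaceMatrix:
    """Distogram of the interface that generates the axis.

    Rows and columns are the full-length residue numbers of the
    (angularly ordered) reference chain and its successor.
    """
    cfg = config or PipelineConfig()
    olig = complex_.oligomer
    ref = olig.model.get_chain(complex_.chain_order[0])
    succ = olig.model.get_chain(complex_.chain_order[1])
    if ref.res_ids != succ.res_ids:
        raise ValueError("chains of a homo-oligomer must share numbering")
    values = min_residue_distances(olig.model, ref, succ, cfg.d_cap)
    if not (values < cfg.d_cap).any():
        raise NoInterfaceError(
            f"{complex_.name}: no inter-chain atom pair below "
            f"{cfg.d_cap} A")
    res_ids = olig.full_res_ids(ref)
    return InterfaceMatrix(values=values, res_ids=res_ids, d_cap=cfg.d_cap)


def matrix_correlation(m1: InterfaceMatrix, m2: InterfaceMatrix,
                       config: PipelineConfig | None = None) -> float:
    """Pearson correlation of binarised distograms on shared positions.

    Entries below the contact cutoff count as contacts; the correlation
    is computed over the full-length index range shared by both
    matrices.  Zero variance in either indicator vector yields 0.
    """
    cfg = config or PipelineConfig()
    shared = np.intersect1d(m1.res_ids, m2.res_ids)
    if shared.size < cfg.min_shared_positions:
        raise ValueError(
            f"only {shared.size} shared full-length positions")
    i1 = np.searchsorted(m1.res_ids, shared)
    i2 = np.searchsorted(m2.res_ids, shared)
    v1 = m1.contacts(cfg.contact_cutoff)[np.ix_(i1, i1)].ravel().astype(float)
    v2 = m2.contacts(cfg.contact_cutoff)[np.ix_(i2, i2)].ravel().astype(float)
    if v1.std() == 0.0 or v2.std() == 0.0:
        warnings.warn("zero-variance contact vector; correlation set to 0")
        return 0.0
    return float(np.corrcoef(v1, v2)[0, 1])


def build_graph(complexes: list[SymmetryComplex],
                config: PipelineConfig | None = None) -> nx.Graph:
    """All-pairs interface-correlation graph.

    Nodes are complex names (inserted in sorted order so that downstream
    partitioning is permutation-invariant); edges carry weights above
    `w_min`.
    """
    cfg = config or PipelineConfig()
    graph = nx.Graph()
    by_name = {}
    for sc in complexes:
        if sc.interface is None:
            sc.interface = interface_matrix(sc, cfg)
        by_name[sc.name] = sc
    for name in sorted(by_name):
        graph.add_node(name, complex=by_name[name])
    names = sorted(by_name)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = by_name[names[i]], by_name[names[j]]
            try:
                w = matrix_correlation(a.interface, b.interface, cfg)
            except ValueError:
                continue
            if w > cfg.w_min:
                graph.add_edge(names[i], names[j], weight=w)
    return graph


@dataclass
class AxisCluster:
    """A community of symmetry complexes sharing one binding interface."""

    members: list[SymmetryComplex]
    consensus_order: int
    representative: SymmetryComplex
    support: list[int] = field(default_factory=list)  # distinct copy counts

    def __post_init__(self):
        if self.representative not in self.members:
            raise ValueError("representative must be a member")
        if self.consensus_order not in (2, 3, 4, 5, 6):
            raise ValueError("consensus order outside supported range")


def _derive_seed(seed: int, names) -> int:
    """Stable per-node-set seed so node order cannot matter."""
    digest = hashlib.md5(",".join(sorted(names)).encode()).digest()
    return (seed ^ int.from_bytes(digest[:4], "big")) % (2 ** 31)


def louvain_partition(graph: nx.Graph,
                      seed: int = 17) -> list[AxisCluster]:
    """Louvain communities of the interface graph as axis clusters.

    The consensus axis order of a cluster is a score-weighted vote among
    members (ties go to the higher order: partial representations with
    several copy counts pointing at one axis are the strongest signal);
    the representative is the highest-scoring member.
    """
    if graph.number_of_nodes() == 0:
        return []
    communities = nx.community.louvain_communities(
        graph, weight="weight",
        seed=_derive_seed(seed, graph.nodes))
    clusters = []
    for community in communities:
        members = sorted((graph.nodes[n]["complex"] for n in community),
                         key=lambda sc: sc.name)
        votes: dict[int, float] = {}
        for sc in members:
            votes[sc.axis.order_k] = votes.get(sc.axis.order_k, 0.0) + sc.score
        consensus = max(votes, key=lambda k: (votes[k], k))
        rep = max(members, key=lambda sc: (sc.score, sc.name))
        support = sorted({sc.oligomer.n_copies for sc in members})
        clusters.append(AxisCluster(members=members, consensus_order=consensus,
                                    representative=rep, support=support))
    clusters.sort(key=lambda c: (-c.representative.score,
                                 c.representative.name))
    return clusters


def rank_pairs(clusters: list[AxisCluster], max_fallback: int = 10):
    """Candidate (cluster_A, cluster_B, rep_A, rep_B) pairs, best first.

    Primary pairs use cluster representatives, ordered by the minimum of
    the two representative scores (descending; ties broken by the higher
    combined axis order).  Fallback pairs drawing on lower-scored
    members are appended for when the leading pair fails assembly.
    """
    if len(clusters) < 2:
        raise OneAxisOnlyError(
            "only one axis cluster: spanning a 2D layer is not possible")
    pairs = []
    seen = set()
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            a, b = clusters[i], clusters[j]
            for ma in a.members[:max_fallback]:
                for mb in b.members[:max_fallback]:
                    key = (ma.name, mb.name)
                    if key in seen:
                        continue
                    seen.add(key)
                    primary = (ma is a.representative
                               and mb is b.representative)
                    pairs.append((a, b, ma, mb, primary))
    pairs.sort(key=lambda p: (
        not p[4],                                   # representatives first
        -min(p[2].score, p[3].score),
        -(p[2].axis.order_k + p[3].axis.order_k),
        p[2].name, p[3].name))
    return [(a, b, ma, mb) for a, b, ma, mb, _ in pairs]
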