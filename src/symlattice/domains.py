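"""Structure-based domain segmentation and subchain generation.

Segmentation runs in three stages on a monomer with assigned secondary
structure:

1. *initial subsections* -- consecutive secondary-structure elements are
   chained into one subsection while they share at least `k_link`
   residue-residue contacts at 5 A (local crosslinking);
2. *iterative merging* -- adjacent subsections are greedily merged by the
   score s(i,j) = contacts(i,j) / sqrt(min(surface_i, surface_j)) /
   sqrt(min(len_i, len_j)) until the best score drops below `tau_merge`
   (saturation);
3. *linker cropping* -- each domain boundary is moved to the residue
   inside the inter-domain linker that minimises contacts crossing the
   cut (ties resolved towards the linker midpoint).

From the final partition a set of five subchains is derived for oligomer
prediction: the full length, the chain without its N-terminal domain,
without its C-terminal domain, the first third of the domains and the
last third of the domains (ceil(D/3) domains each), clamped to
configured minimum/maximum lengths.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .config import PipelineConfig
from .geometry import contact_count, surface_area
from .structure import Chain, StructureModel


@dataclass
class DomainPartition:
    """Ordered, disjoint [start, end] residue intervals (1-based, incl.)."""

    intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        prev_end = None
        for s, e in self.intervals:
            if s > e:
                raise ValueError(f"interval ({s}, {e}) reversed")
            if prev_end is not None and s <= prev_end:
                raise ValueError("intervals must be sorted and disjoint")
            prev_end = e

    def __len__(self):
        return len(self.intervals)

    def lengths(self):
        return [e - s + 1 for s, e in self.intervals]


@dataclass
class SubchainSpec:
    """A truncation of the full chain used for oligomer prediction."""

    id: str                      # full | no_nterm | no_cterm | first_third |
                                 # last_third | single_domain:<k>
    interval: tuple[int, int]
    domain_ids: list[int] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0] + 1


def _sel(chain: Chain, start: int, end: int):
    return [(chain.chain_id, r) for r in chain.res_ids if start <= r <= end]


def _sse_segments(chain: Chain):
    """Maximal runs of H or E as (start_res_id, end_res_id)."""
    if chain.sse is None:
        raise ValueError("secondary structure not assigned")
    segs = []
    cur = None
    for rid, label in zip(chain.res_ids, chain.sse):
        if label in ("H", "E"):
            if cur is None:
                cur = [rid, rid]
            else:
                cur[1] = rid
        else:
            if cur is not None:
                segs.append(tuple(cur))
                cur = None
    if cur is not None:
        segs.append(tuple(cur))
    return segs


def initial_subsections(model: StructureModel,
                        config: PipelineConfig | None = None,
                        chain_id: str | None = None):
    """Chain ranges from local crosslinking of secondary structures.

    Consecutive SSE segments stay in one subsection while they share at
    least `k_link` residue contacts; intervening coil is split halfway
    between neighbouring subsections.  An all-coil chain yields a single
    interval with a warning.
    """
    cfg = config or PipelineConfig()
    chain = model.get_chain(chain_id) if chain_id else model.chains[0]
    lo, hi = chain.res_ids[0], chain.res_ids[-1]
    # isolated 1-2 residue SSE calls are noise, not subsection seeds
    segs = [s for s in _sse_segments(chain) if s[1] - s[0] + 1 >= 3]
    if not segs:
        warnings.warn("all-coil chain: one subsection per chain")
        return [(lo, hi)]
    groups = [[segs[0]]]
    for seg in segs[1:]:
        prev = groups[-1][-1]
        n = contact_count(model, _sel(chain, *prev), _sel(chain, *seg),
                          cfg.contact_cutoff)
        if n >= cfg.k_link:
            groups[-1].append(seg)
        else:
            groups.append([seg])
    # cores, then stretch over the coil between groups
    cores = [(g[0][0], g[-1][1]) for g in groups]
    intervals = []
    for i, (s, e) in enumerate(cores):
        start = lo if i == 0 else (cores[i - 1][1] + s) // 2 + 1
        end = hi if i == len(cores) - 1 else (e + cores[i + 1][0]) // 2
        intervals.append((start, end))
    return intervals


def _nonlocal_contacts(model: StructureModel, chain: Chain, iv_a, iv_b,
                       cfg: PipelineConfig) -> int:
    """Residue contacts between two intervals, excluding pairs that are
    trivially close in sequence (|i - j| <= 2): covalent adjacency along
    the chain is not interface evidence."""
    from .geometry import contact_pairs
    pairs = contact_pairs(model, _sel(chain, *iv_a), _sel(chain, *iv_b),
                          cfg.contact_cutoff)
    return sum(1 for (ca, ra), (cb, rb) in pairs
               if ca != cb or abs(ra - rb) > 2)


def _merge_score(model: StructureModel, chain: Chain,
                 iv_a, iv_b, cfg: PipelineConfig,
                 surf_cache: dict) -> float:
    contacts = _nonlocal_contacts(model, chain, iv_a, iv_b, cfg)
    if contacts == 0:
        return 0.0

    def surf(iv):
        if iv not in surf_cache:
            surf_cache[iv] = surface_area(model, _sel(chain, *iv),
                                          probe=cfg.probe_radius,
                                          n_points=cfg.sphere_points)
        return surf_cache[iv]

    len_a = iv_a[1] - iv_a[0] + 1
    len_b = iv_b[1] - iv_b[0] + 1
    s_min = max(min(surf(iv_a), surf(iv_b)), 1.0)
    return contacts / (math.sqrt(s_min) * math.sqrt(min(len_a, len_b)))


def merge_to_domains(model: StructureModel, subsections,
                     config: PipelineConfig | None = None,
                     chain_id: str | None = None) -> DomainPartition:
    """Greedy merging of adjacent subsections until score saturation.

    The adjacent pair with the largest merge score is merged; merging
    stops once the best score falls below `tau_merge`.  Ties go to the
    lower start index, so the procedure is deterministic.
    """
    cfg = config or PipelineConfig()
    chain = model.get_chain(chain_id) if chain_id else model.chains[0]
    intervals = sorted(subsections)
    surf_cache: dict = {}
    while len(intervals) > 1:
        scores = [
            _merge_score(model, chain, intervals[i], intervals[i + 1],
                         cfg, surf_cache)
            for i in range(len(intervals) - 1)]
        best = max(range(len(scores)), key=lambda i: (scores[i], -i))
        if scores[best] < cfg.tau_merge:
            break
        merged = (intervals[best][0], intervals[best + 1][1])
        intervals[best:best + 2] = [merged]
    # absorb fragments below the minimum domain length into a neighbour
    changed = True
    while changed and len(intervals) > 1:
        changed = False
        for i, iv in enumerate(intervals):
            if iv[1] - iv[0] + 1 < cfg.min_domain_len:
                if i + 1 < len(intervals):
                    intervals[i:i + 2] = [(iv[0], intervals[i + 1][1])]
                else:
                    intervals[i - 1:i + 1] = [(intervals[i - 1][0], iv[1])]
                changed = True
                break
    return DomainPartition(intervals=intervals)


def crop_linkers(model: StructureModel, partition: DomainPartition,
                 config: PipelineConfig | None = None,
                 chain_id: str | None = None) -> DomainPartition:
    """Move each boundary to the cut minimising cross-boundary contacts.

    The candidate cuts are the coil residues spanning the current
    boundary; the cut with the fewest contacts between the two sides
    wins, ties resolved towards the linker midpoint (then the lower
    index).  A zero-length linker leaves the boundary unchanged.
    """
    cfg = config or PipelineConfig()
    chain = model.get_chain(chain_id) if chain_id else model.chains[0]
    if len(partition) < 2:
        return partition
    sse_by_res = dict(zip(chain.res_ids, chain.sse)) if chain.sse is not None else {}
    intervals = list(partition.intervals)
    for b in range(len(intervals) - 1):
        start_a = intervals[b][0]
        end_b = intervals[b + 1][1]
        boundary = intervals[b][1]
        # linker: maximal coil run containing the boundary
        linker_lo = boundary
        while linker_lo - 1 >= start_a and sse_by_res.get(linker_lo, "C") == "C" \
                and sse_by_res.get(linker_lo - 1, "C") == "C":
            linker_lo -= 1
        linker_hi = boundary
        while linker_hi + 1 <= end_b - 1 \
                and sse_by_res.get(linker_hi + 1, "C") == "C":
            linker_hi += 1
        candidates = [c for c in range(linker_lo, linker_hi + 1)
                      if start_a <= c < end_b]
        if not candidates:
            continue
        mid = 0.5 * (linker_lo + linker_hi)
        best = None
        for cut in candidates:
            n = _nonlocal_contacts(model, chain, (start_a, cut),
                                   (cut + 1, end_b), cfg)
            key = (n, abs(cut - mid), cut)
            if best is None or key < best[0]:
                best = (key, cut)
        cut = best[1]
        intervals[b] = (start_a, cut)
        intervals[b + 1] = (cut + 1, end_b)
    return DomainPartition(intervals=intervals)


def identify_domains(model: StructureModel,
                     config: PipelineConfig | None = None,
                     chain_id: str | None = None) -> DomainPartition:
    """Full segmentation: crosslinking, merging, linker cropping."""
    subs = initial_subsections(model, config, chain_id)
    part = merge_to_domains(model, subs, config, chain_id)
    return crop_linkers(model, part, config, chain_id)


def _clamp(interval, anchor: str, chain_lo: int, chain_hi: int,
           cfg: PipelineConfig):
    """Clamp an interval into [min_len, max_len], keeping its anchor end."""
    s, e = interval
    length = e - s + 1
    if length < cfg.subchain_min_len:
        need = cfg.subchain_min_len - length
        if anchor == "start":
            e = min(e + need, chain_hi)
        else:
            s = max(s - need, chain_lo)
    length = e - s + 1
    if length > cfg.subchain_max_len:
        if anchor == "start":
            e = s + cfg.subchain_max_len - 1
        else:
            s = e - cfg.subchain_max_len + 1
    return (s, e)


def make_subchains(partition: DomainPartition, chain_len: int,
                   config: PipelineConfig | None = None,
                   chain_start: int = 1):
    """The five-subchain truncation scheme.

    full length, no N-terminal domain, no C-terminal domain, first
    ceil(D/3) domains, last ceil(D/3) domains.  Duplicate intervals are
    collapsed with a warning; a single-domain protein yields only the
    full-length subchain (flagged by the short list).
    """
    cfg = config or PipelineConfig()
    if len(partition) == 0:
        raise ValueError("empty partition")
    ivs = partition.intervals
    lo = chain_start
    hi = chain_start + chain_len - 1
    d = len(ivs)
    if d == 1:
        warnings.warn("single-domain protein: full-length subchain only")
        return [SubchainSpec("full", (lo, hi), [0])]
    third = math.ceil(d / 3)
    raw = [
        ("full", (lo, hi), list(range(d)), "start"),
        ("no_nterm", (ivs[1][0], hi), list(range(1, d)), "end"),
        ("no_cterm", (lo, ivs[d - 2][1]), list(range(d - 1)), "start"),
        ("first_third", (lo, ivs[third - 1][1]), list(range(third)), "start"),
        ("last_third", (ivs[d - third][0], hi),
         list(range(d - third, d)), "end"),
    ]
    specs, seen = [], {}
    for sid, iv, dom_ids, anchor in raw:
        iv = _clamp(iv, anchor, lo, hi, cfg)
        if iv in seen:
            warnings.warn(f"subchain {sid} duplicates {seen[iv]}; collapsed")
            continue
        seen[iv] = sid
        specs.append(SubchainSpec(sid, iv, dom_ids))
    return specs


def p1_single_domains(partition: DomainPartition):
    """One subchain per domain (p1 heterodimer route); sorted by start."""
    if len(partition) < 2:
        raise ValueError(
            "single-domain protein: use the standard subchain scheme")
    return [SubchainSpec(f"single_domain:{k}", iv, [k])
            for k, iv in enumerate(sorted(partition.intervals))]


def domain_report(model: StructureModel, partition: DomainPartition,
                  config: PipelineConfig | None = None,
                  chain_id: str | None = None) -> str:
    """TSV per-domain report: id, start, end, length, surface area."""
    cfg = config or PipelineConfig()
    chain = model.get_chain(chain_id) if chain_id else model.chains[0]
    lines = ["domain_id\tstart\tend\tlen\tsurface_A2"]
    for k, (s, e) in enumerate(partition.intervals):
        area = surface_area(model, _sel(chain, s, e),
                            probe=cfg.probe_radius,
                            n_points=cfg.sphere_points)
        lines.append(f"{k}\t{s}\t{e}\t{e - s + 1}\t{area:.1f}")
    return "\n".join(lines) + "\n"


def domain_sequences(chain: Chain, partition: DomainPartition):
    """One-letter sequences of each domain (for the domain FASTA)."""
    seq_by_res = dict(zip(chain.res_ids, chain.sequence))
    out = []
    for s, e in partition.intervals:
        out.append("".join(seq_by_res[r] for r in chain.res_ids
                           if s <= r <= e))
    return out
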