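"""Model-quality gates applied to candidate symmetry complexes.

Four criteria decide whether an oligomer prediction survives:

* a rotational symmetry axis (handled by :mod:`symlattice.symmetry`),
* the weighted confidence score -- at least 0.3 at the homodimer
  pre-filter, at least 0.2 at the symmetry stage,
* steric clashes -- relaxed models are excluded at >= 3.0 intermolecular
  clashes per 100 aa of the protein chain, or when any 200-aa sequence
  window exceeds 6.0 clashes per 100 aa (unrelaxed thresholds are 20x
  looser: 60.0 and 120.0),
* no unusually high fraction of intermolecular beta-strand pairing.

A clash is an inter-chain heavy-atom pair closer than
r_i + r_j - overlap_allowance (0.6 A).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .config import PipelineConfig, vdw_radius
from .geometry import contact_count, chain_selection
from .io import ScoredOligomer
from .structure import StructureModel


@dataclass
class ClashReport:
    n_clashes: int                 # intermolecular atom-pair clashes
    n_res: int                     # residues in the full protein chain
    per_window: int                # max clashes in any 200-aa window
    window_len: int
    relaxed: bool = True

    def __post_init__(self):
        if self.n_clashes < 0 or self.per_window < 0:
            raise ValueError("clash counts must be non-negative")
        if self.per_window > self.n_clashes:
            raise ValueError("windowed count cannot exceed the total")

    @property
    def per_100aa(self) -> float:
        return 100.0 * self.n_clashes / self.n_res


def clash_pairs(model: StructureModel, config: PipelineConfig | None = None,
                residue_offset: int = 0):
    """Inter-chain heavy-atom clashes as (pos_a, pos_b) residue positions.

    Positions are author residue numbers shifted by `residue_offset`
    into full-length numbering.
    """
    cfg = config or PipelineConfig()
    coords, radii, chain_idx, positions = [], [], [], []
    for ci, ch in enumerate(model.chains):
        heavy = ch.heavy_mask
        res = ch.atom_res
        for i in np.nonzero(heavy)[0]:
            coords.append(ch.coords[i])
            radii.append(vdw_radius(ch.elements[i]))
            chain_idx.append(ci)
            positions.append(ch.res_ids[res[i]] + residue_offset)
    coords = np.array(coords)
    radii = np.array(radii)
    chain_idx = np.array(chain_idx)
    positions = np.array(positions)

    max_reach = 2 * radii.max() - cfg.clash_overlap
    tree = cKDTree(coords)
    clash_pos = []
    for ia, ib in tree.query_pairs(max_reach):
        if chain_idx[ia] == chain_idx[ib]:
            continue
        limit = radii[ia] + radii[ib] - cfg.clash_overlap
        if np.linalg.norm(coords[ia] - coords[ib]) < limit:
            clash_pos.append((positions[ia], positions[ib]))
    return clash_pos


def count_clashes(oligomer: ScoredOligomer,
                  config: PipelineConfig | None = None) -> ClashReport:
    """Count inter-chain heavy-atom clashes and the worst sequence window.

    The windowed count slides a `clash_window_len` (200 aa) window over
    full-length residue numbering; a clash falls into a window when
    either participating residue position lies inside it.
    """
    cfg = config or PipelineConfig()
    model = oligomer.model
    clash_pos = clash_pairs(model, cfg, oligomer.residue_offset)

    length = oligomer.chain_length
    win = min(cfg.clash_window_len, length)
    lo = min(p + oligomer.residue_offset
             for p in model.chains[0].res_ids) if model.chains else 1
    hi = lo + length - 1
    per_window = 0
    if clash_pos:
        starts = range(lo, hi - win + 2)
        arr = np.array(clash_pos)
        for s in starts:
            e = s + win - 1
            inside = ((arr >= s) & (arr <= e)).any(axis=1)
            per_window = max(per_window, int(inside.sum()))
    return ClashReport(n_clashes=len(clash_pos), n_res=length,
                       per_window=per_window, window_len=win,
                       relaxed=oligomer.score.relaxed)


def score_gate(score: float, stage: str,
               config: PipelineConfig | None = None) -> bool:
    """Confidence-score gate: prefilter >= 0.3, symmetry stage >= 0.20."""
    cfg = config or PipelineConfig()
    if stage == "prefilter":
        return score >= cfg.min_score_prefilter
    if stage == "symmetry":
        return score >= cfg.min_score_symmetry
    raise ValueError(f"unknown stage {stage!r}")


def clash_gate(report: ClashReport,
               config: PipelineConfig | None = None):
    """Clash thresholds; returns (passed, reasons).

    The global rule is exclusive at the threshold (a model *at* 3.0
    clashes per 100 aa is excluded); the window rule is inclusive (only
    counts strictly above the allowance fail).
    """
    cfg = config or PipelineConfig()
    if report.relaxed:
        glob, wind = cfg.clash_global_relaxed, cfg.clash_window_relaxed
    else:
        glob, wind = cfg.clash_global_unrelaxed, cfg.clash_window_unrelaxed
    reasons = []
    if report.per_100aa >= glob:
        reasons.append("global_clash")
    if report.per_window > wind * report.window_len / 100.0:
        reasons.append("window_clash")
    return (not reasons, reasons)


def beta_fraction(model: StructureModel) -> float:
    """Fraction of residues engaged in inter-chain beta bridges."""
    if model.n_res == 0:
        return 0.0
    inter = set()
    for (ca, ra), (cb, rb) in model.bridge_partners:
        if ca != cb:
            inter.add((ca, ra))
            inter.add((cb, rb))
    return len(inter) / model.n_res


def beta_gate(oligomer: ScoredOligomer,
              config: PipelineConfig | None = None) -> bool:
    """Reject models whose inter-chain beta pairing exceeds beta_max."""
    cfg = config or PipelineConfig()
    return beta_fraction(oligomer.model) <= cfg.beta_max


@dataclass
class FilterOutcome:
    passed: bool
    reasons: list[str] = field(default_factory=list)
    clash_report: ClashReport | None = None

    def __post_init__(self):
        if self.passed != (not self.reasons):
            raise ValueError("passed flag inconsistent with reasons")


def has_interface(oligomer: ScoredOligomer,
                  config: PipelineConfig | None = None) -> bool:
    """At least one inter-chain residue contact at the contact cutoff."""
    cfg = config or PipelineConfig()
    chains = oligomer.model.chains
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            if contact_count(oligomer.model, chain_selection(chains[i]),
                             chain_selection(chains[j]),
                             cfg.contact_cutoff) > 0:
                return True
    return False


def apply_filters(oligomer: ScoredOligomer, mode: str = "layer",
                  config: PipelineConfig | None = None) -> FilterOutcome:
    """Evaluate every gate (no short-circuit) so reasons are complete."""
    cfg = config or PipelineConfig()
    reasons = []
    if not score_gate(oligomer.score.combined, "symmetry", cfg):
        reasons.append("low_score")
    report = count_clashes(oligomer, cfg)
    _, clash_reasons = clash_gate(report, cfg)
    reasons.extend(clash_reasons)
    if not beta_gate(oligomer, cfg):
        reasons.append("beta_strand")
    if not has_interface(oligomer, cfg):
        reasons.append("no_interface")
    return FilterOutcome(passed=not reasons, reasons=reasons,
                         clash_report=report)
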