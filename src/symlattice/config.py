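"""Pipeline configuration.

All numeric gates of the pipeline live here so that a single YAML file
documents every threshold applied to a run.  The defaults encode the
published operating point of the method: oligomer models are kept when
their weighted confidence score (0.8*ipTM + 0.2*pTM) reaches 0.3 at the
homodimer pre-filter and 0.2 at the symmetry stage, rotational axes must
be uniform to within 5 A per monomer, and relaxed models are discarded at
3.0 clashes per 100 aa globally or above 6.0 per 100 aa inside any 200-aa
sequence window (20x looser for unrelaxed models).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

# van der Waals radii (A) used for clash and surface calculations.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
DEFAULT_VDW_RADIUS = 1.70


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)


@dataclass
class PipelineConfig:
    """Every tunable of the lattice-assembly pipeline, with defaults."""

    # run mode: flat 2D layer, p1 (heterodimer route), or curved capsid tile
    mode: str = "layer"

    # confidence-score gates (0.8*ipTM + 0.2*pTM scale)
    min_score_prefilter: float = 0.30
    min_score_symmetry: float = 0.20

    # rotational-axis acceptance
    angle_tol: float = 10.0        # deg, |delta_phi - 360/k| tolerance
    axis_dev_max: float = 5.0      # A, max per-monomer deviation from ideal axis
    screw_tol: float = 3.0         # A per step, layer mode only

    # clash counting and gates
    clash_overlap: float = 0.6     # A subtracted from r_i + r_j
    clash_global_relaxed: float = 3.0     # clashes per 100 aa, >= excludes
    clash_global_unrelaxed: float = 60.0
    clash_window_relaxed: float = 6.0     # per 100 aa in a window, > excludes
    clash_window_unrelaxed: float = 120.0
    clash_window_len: int = 200    # aa

    # intermolecular beta-strand filter
    beta_max: float = 0.25         # max fraction of residues in inter-chain bridges

    # interfaces and clustering
    contact_cutoff: float = 5.0    # A, residue-residue contact definition
    d_cap: float = 10.0            # A, distogram cap
    w_min: float = 0.2             # min interface correlation kept as an edge
    min_shared_positions: int = 20  # min shared full-length positions for a correlation

    # superposition / termination
    gap_max: float = 5.0           # A overlap RMSD above which complexes cannot connect
    tilt_max: float = 45.0         # deg, axis tilt termination
    cell_dev_max: float = 0.10     # relative lattice-constant deviation termination
    rigid_max: float = 2.5         # A, median intra-monomer pairwise RMSD termination

    # domain segmentation
    k_link: int = 8                # residue contacts linking consecutive SSE segments
    tau_merge: float = 0.01        # merge-score saturation threshold
    min_domain_len: int = 25       # aa
    subchain_min_len: int = 120    # aa, clamp for generated subchains
    subchain_max_len: int = 1200   # aa

    # surface sampling
    probe_radius: float = 1.4      # A
    sphere_points: int = 240

    seed: int = 17

    def allowed_orders(self) -> frozenset[int]:
        """Axis orders accepted in this mode (5-fold only on curved shells)."""
        if self.mode == "capsid":
            return frozenset({2, 3, 4, 5, 6})
        return frozenset({2, 3, 4, 6})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    def validate(self) -> None:
        if self.mode not in ("layer", "p1", "capsid"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for key in ("min_score_prefilter", "min_score_symmetry"):
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{key} must be in [0,1], got {v}")
        for key in ("angle_tol", "axis_dev_max", "gap_max", "tilt_max",
                    "contact_cutoff", "d_cap", "clash_overlap"):
            if getattr(self, key) <= 0:
                raise ValueError(f"{key} must be positive")
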