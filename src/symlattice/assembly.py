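"""Superposition of two symmetry axes into a repeating 2D lattice.

Of a pair of symmetry complexes the one with the higher axis order (A)
is aligned with its axis along +z; copies of the other (B) are placed by
least-squares superposition of the shared-domain residues onto each A
monomer, then re-rotated so their axes are parallel to z about a pivot
in the linker joining shared and non-shared domains.  Copies of A are
propagated onto the B monomers in the same way, producing a lattice
patch.  The patch is scored by

    score_clash   = N_clashes / N_res                       (per residue)
    score_bend    = (2/pi) * sqrt(mean(phi_i^2))            (0 flat, 1 at 90 deg)
    score_quality = score_clash + score_bend

with phi_i the tilt of the i-th placed B axis against the central axis.
Unit-cell vectors are the symmetry-averaged xy-translations from the
central to the propagated A complexes; the cell is snapped to the
wallpaper group implied by the axis orders and written to mmCIF with
explicit symmetry operators.  Termination mirrors the published rules:
axis tilt above 45 deg, an overlap gap that cannot be bridged, a lattice
constant deviating from the superposed model, or a non-rigid folding
unit each abort the assembly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .config import PipelineConfig
from .filters import clash_pairs
from .structure import Chain, StructureModel
from .symmetry import (RigidTransform, SymmetryAxis, SymmetryComplex,
                       kabsch)

WALLPAPER_SPACEGROUP = {
    "p1": "P 1", "p2": "P 1 1 2", "p3": "P 3", "p4": "P 4", "p6": "P 6",
}
CELL_C = 500.0   # A; slab thickness of the 3D cell embedding the 2D lattice


class CannotConnectError(RuntimeError):
    """A and B share no domain: overlap superposition is impossible."""


class GapTooLargeError(RuntimeError):
    """Overlap RMSD above gap_max: the complexes cannot be connected."""

    def __init__(self, rmsd: float, limit: float):
        super().__init__(f"overlap RMSD {rmsd:.2f} A exceeds {limit:.2f} A")
        self.rmsd = rmsd


class CollinearVectorsError(RuntimeError):
    """Propagated translations span only one direction."""


class P1InsufficientError(RuntimeError):
    """Fewer than two strong heterodimer interactions."""


class DegenerateCellError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# placements
# ---------------------------------------------------------------------------

@dataclass
class PlacedComplex:
    """A symmetry complex after a rigid placement into the tile frame."""

    source: SymmetryComplex
    model: StructureModel
    axis: SymmetryAxis
    transform: RigidTransform
    overlap_rmsd: float = 0.0
    raw_direction: np.ndarray | None = None   # axis before re-parallelisation

    def __post_init__(self):
        if self.raw_direction is None:
            self.raw_direction = self.axis.direction.copy()

    def tilt_to(self, direction: np.ndarray) -> float:
        """Angle (deg) between the as-placed axis and `direction`."""
        c = abs(float(np.dot(self.raw_direction, direction)))
        return math.degrees(math.acos(min(1.0, c)))


def _transform_axis(axis: SymmetryAxis, tf: RigidTransform) -> SymmetryAxis:
    d = tf.rotation @ axis.direction
    return SymmetryAxis(direction=d / np.linalg.norm(d),
                        anchor=tf.apply(axis.anchor),
                        order_k=axis.order_k, delta_phi=axis.delta_phi,
                        filled=axis.filled,
                        per_monomer_dev=list(axis.per_monomer_dev),
                        screw_shift=axis.screw_shift)


def _apply_placement(sc: SymmetryComplex, tf: RigidTransform,
                     overlap_rmsd: float = 0.0) -> PlacedComplex:
    model = sc.oligomer.model.copy()
    model.transform(tf.rotation, tf.translation)
    return PlacedComplex(source=sc, model=model,
                         axis=_transform_axis(sc.axis, tf),
                         transform=tf, overlap_rmsd=overlap_rmsd)


def _minimal_rotation_to(d_from: np.ndarray, d_to: np.ndarray) -> np.ndarray:
    """Smallest proper rotation matrix mapping d_from onto d_to."""
    a = d_from / np.linalg.norm(d_from)
    b = d_to / np.linalg.norm(d_to)
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    c = float(np.dot(a, b))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180 deg: rotate about any axis perpendicular to a
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return Rotation.from_rotvec(math.pi * perp).as_matrix()
    return Rotation.from_rotvec(v / s * math.atan2(s, c)).as_matrix()


def align_axis_to_z(sc: SymmetryComplex) -> PlacedComplex:
    """Place a complex with its axis along +z through the origin."""
    R = _minimal_rotation_to(sc.axis.direction, np.array([0.0, 0.0, 1.0]))
    t = -R @ sc.axis.anchor
    return _apply_placement(sc, RigidTransform(R, t))


@dataclass
class AssemblyTile:
    """Central complex A, placed B copies and propagated A copies."""

    central_A: PlacedComplex
    B_copies: list[PlacedComplex] = field(default_factory=list)
    peripheral_A: list[PlacedComplex] = field(default_factory=list)

    @property
    def overlap_rmsds(self):
        return ([p.overlap_rmsd for p in self.B_copies]
                + [p.overlap_rmsd for p in self.peripheral_A])

    def tilt_angles(self):
        """Tilt (deg) of each placed B axis against the central axis."""
        d0 = self.central_A.axis.direction
        return [p.tilt_to(d0) for p in self.B_copies]

    def merged_model(self, dedup_tol: float = 3.0) -> StructureModel:
        """All placements as one model, duplicate monomers dropped.

        Overlapping placements share monomers by construction; chains
        whose CA centroid lies within `dedup_tol` of an already-included
        chain are duplicates, not contacts, and are removed before
        clash counting.
        """
        merged = StructureModel(name="tile")
        centroids = []
        counter = 0
        for placed in [self.central_A, *self.B_copies, *self.peripheral_A]:
            for ch in placed.model.chains:
                cen = np.nanmean(ch.ca_coords(), axis=0)
                if any(np.linalg.norm(cen - c) < dedup_tol for c in centroids):
                    continue
                dup = ch.copy()
                dup.chain_id = f"{chr(65 + counter % 26)}{counter // 26}"
                counter += 1
                merged.add_chain(dup)
                centroids.append(cen)
        return merged


def _matched_ca_by_full_ids(oligomer, chain: Chain, full_res_ids):
    """CA coordinates of `chain` at the given full-length residue ids."""
    wanted = [int(r) - oligomer.residue_offset for r in full_res_ids]
    ca = chain.ca_coords()
    out, used = [], []
    index = {rid: i for i, rid in enumerate(chain.res_ids)}
    for rid in wanted:
        i = index.get(rid)
        if i is not None and np.all(np.isfinite(ca[i])):
            out.append(ca[i])
            used.append(rid + oligomer.residue_offset)
    return np.array(out), used


def _superpose_on_chain(source_sc: SymmetryComplex, source_chain_id: str,
                        target_model: StructureModel, target_chain_id: str,
                        target_offset: int, shared_res, cfg: PipelineConfig):
    """Transform placing `source` so its chain matches the target chain."""
    src_chain = source_sc.oligomer.model.get_chain(source_chain_id)
    a_coords, used = _matched_ca_by_full_ids(source_sc.oligomer, src_chain,
                                             shared_res)
    tgt_chain = target_model.get_chain(target_chain_id)
    ca = tgt_chain.ca_coords()
    index = {rid + target_offset: i for i, rid in enumerate(tgt_chain.res_ids)}
    b_coords = []
    a_keep = []
    for pos, ac in zip(used, a_coords):
        i = index.get(pos)
        if i is not None and np.all(np.isfinite(ca[i])):
            b_coords.append(ca[i])
            a_keep.append(ac)
    if len(b_coords) < 3:
        raise CannotConnectError(
            "fewer than 3 shared residues between the complexes")
    tf, rmsd = kabsch(np.array(a_keep), np.array(b_coords))
    if rmsd > cfg.gap_max:
        raise GapTooLargeError(rmsd, cfg.gap_max)
    return tf, rmsd


def place_B_copies(tile: AssemblyTile, complex_B: SymmetryComplex,
                   shared_res, pivot_res=None, realign: bool = True,
                   config: PipelineConfig | None = None) -> AssemblyTile:
    """Superpose one copy of B onto every monomer of the central A.

    `shared_res` are full-length residue numbers of the shared domain(s);
    `pivot_res` the linker residues used as pivot when re-rotating each
    placed B axis parallel to z (`realign=False` keeps the as-superposed
    orientation, as on curved shells).
    """
    cfg = config or PipelineConfig()
    shared_res = list(shared_res)
    if not shared_res:
        raise CannotConnectError("no shared domain between A and B")
    central = tile.central_A
    b_ref_chain = complex_B.chain_order[0]
    d0 = central.axis.direction
    for a_chain_id in central.source.chain_order:
        tf, rmsd = _superpose_on_chain(
            complex_B, b_ref_chain, central.model, a_chain_id,
            central.source.oligomer.residue_offset, shared_res, cfg)
        placed = _apply_placement(complex_B, tf, overlap_rmsd=rmsd)
        placed.raw_direction = placed.axis.direction.copy()
        if realign:
            target = d0 if np.dot(placed.axis.direction, d0) >= 0 else -d0
            R = _minimal_rotation_to(placed.axis.direction, target)
            if pivot_res:
                ref = placed.model.get_chain(b_ref_chain)
                pts, _ = _matched_ca_by_full_ids(complex_B.oligomer, ref,
                                                 pivot_res)
                pivot = (pts.mean(axis=0) if len(pts)
                         else placed.model.centroid())
            else:
                ref = placed.model.get_chain(b_ref_chain)
                pts, _ = _matched_ca_by_full_ids(complex_B.oligomer, ref,
                                                 shared_res)
                pivot = pts.mean(axis=0)
            extra = RigidTransform(R, pivot - R @ pivot)
            placed.model.transform(extra.rotation, extra.translation)
            placed.axis = _transform_axis(placed.axis, extra)
            placed.transform = extra.compose(placed.transform)
        tile.B_copies.append(placed)
    return tile


def propagate_A(tile: AssemblyTile, shared_res,
                config: PipelineConfig | None = None,
                merge_tol: float = 1.0) -> AssemblyTile:
    """Place copies of A on the B monomers, completing the lattice patch.

    Placements whose axis anchor coincides (within `merge_tol` in xy)
    with the central axis or an earlier copy are duplicates and skipped.
    """
    cfg = config or PipelineConfig()
    central = tile.central_A
    a_sc = central.source
    a_ref_chain = a_sc.chain_order[0]
    anchors = [central.axis.anchor[:2]]
    anchors += [p.axis.anchor[:2] for p in tile.peripheral_A]
    d0 = central.axis.direction
    for b_copy in tile.B_copies:
        for b_chain_id in b_copy.source.chain_order:
            tf, rmsd = _superpose_on_chain(
                a_sc, a_ref_chain, b_copy.model, b_chain_id,
                b_copy.source.oligomer.residue_offset, shared_res, cfg)
            placed = _apply_placement(a_sc, tf, overlap_rmsd=rmsd)
            xy = placed.axis.anchor[:2]
            if any(np.linalg.norm(xy - a) < merge_tol for a in anchors):
                continue
            target = d0 if np.dot(placed.axis.direction, d0) >= 0 else -d0
            R = _minimal_rotation_to(placed.axis.direction, target)
            pivot = placed.axis.anchor
            extra = RigidTransform(R, pivot - R @ pivot)
            placed.model.transform(extra.rotation, extra.translation)
            placed.axis = _transform_axis(placed.axis, extra)
            placed.transform = extra.compose(placed.transform)
            anchors.append(xy)
            tile.peripheral_A.append(placed)
    return tile


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

@dataclass
class QualityScores:
    score_clash: float
    score_bend: float

    @property
    def score_quality(self) -> float:
        return self.score_clash + self.score_bend


def bending_score(tile: AssemblyTile) -> float:
    """(2/pi) * RMS of B-axis tilt angles (radians) against the A axis."""
    tilts = tile.tilt_angles()
    if not tilts:
        return 0.0
    phi = np.radians(tilts)
    return float(2.0 / math.pi * math.sqrt(float(np.mean(phi ** 2))))


def clash_score(tile: AssemblyTile,
                config: PipelineConfig | None = None) -> float:
    """Average intermolecular clashes per residue over the merged tile."""
    cfg = config or PipelineConfig()
    merged = tile.merged_model()
    n_res = merged.n_res
    if n_res == 0:
        return 0.0
    return len(clash_pairs(merged, cfg)) / n_res


def quality_score(scores: QualityScores) -> float:
    return scores.score_quality


def score_tile(tile: AssemblyTile,
               config: PipelineConfig | None = None) -> QualityScores:
    return QualityScores(score_clash=clash_score(tile, config),
                         score_bend=bending_score(tile))


def monomer_rigidity(tile: AssemblyTile) -> float:
    """Median pairwise CA RMSD between the central complex's monomers."""
    chains = tile.central_A.model.chains
    rmsds = []
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            shared = sorted(set(chains[i].res_ids) & set(chains[j].res_ids))
            cai, caj = chains[i].ca_coords(), chains[j].ca_coords()
            a = np.array([cai[chains[i].res_index_of(r)] for r in shared])
            b = np.array([caj[chains[j].res_index_of(r)] for r in shared])
            ok = np.all(np.isfinite(a), axis=1) & np.all(np.isfinite(b), axis=1)
            if ok.sum() < 3:
                continue
            _, rmsd = kabsch(a[ok], b[ok])
            rmsds.append(rmsd)
    return float(np.median(rmsds)) if rmsds else 0.0


# ---------------------------------------------------------------------------
# unit cell
# ---------------------------------------------------------------------------

@dataclass
class UnitCell:
    a: float
    b: float
    gamma: float          # degrees
    group: str            # p1 | p2 | p3 | p4 | p6

    def __post_init__(self):
        if self.group not in WALLPAPER_SPACEGROUP:
            raise ValueError(f"unknown wallpaper group {self.group!r}")
        if self.group == "p4" and (abs(self.a - self.b) > 1e-6
                                   or abs(self.gamma - 90.0) > 1e-6):
            raise ValueError("p4 requires a = b, gamma = 90")
        if self.group in ("p3", "p6") and (abs(self.a - self.b) > 1e-6
                                           or abs(self.gamma - 120.0) > 1e-6):
            raise ValueError(f"{self.group} requires a = b, gamma = 120")


@dataclass
class LatticeModel:
    cell: UnitCell
    asym_unit: StructureModel
    symops: list[str]
    scores: QualityScores | None = None

    def lattice_vectors(self) -> np.ndarray:
        g = math.radians(self.cell.gamma)
        return np.array([[self.cell.a, 0.0],
                         [self.cell.b * math.cos(g),
                          self.cell.b * math.sin(g)]])


@dataclass
class CellDraft:
    """Measured (pre-idealisation) cell evidence for the termination check."""

    v1: np.ndarray
    v2: np.ndarray
    lengths_1: list[float]
    lengths_2: list[float]


def _direction_classes(vectors, tol_deg: float = 20.0):
    """Group 2D vectors into +/- direction classes within `tol_deg`."""
    classes: list[list[np.ndarray]] = []
    for v in vectors:
        n = np.linalg.norm(v)
        if n < 1e-6:
            continue
        placed = False
        for cl in classes:
            u = cl[0] / np.linalg.norm(cl[0])
            c = float(np.dot(v / n, u))
            if abs(c) > math.cos(math.radians(tol_deg)):
                cl.append(v if c > 0 else -v)
                placed = True
                break
        if not placed:
            classes.append([v])
    return [np.mean(cl, axis=0) for cl in classes], classes


def group_from_orders(k_a: int, k_b: int) -> str:
    """Wallpaper group implied by the two axis orders (max rules)."""
    k = max(k_a, k_b)
    if k not in (1, 2, 3, 4, 6):
        raise ValueError(f"order {k} has no planar wallpaper group")
    return {1: "p1", 2: "p2", 3: "p3", 4: "p4", 6: "p6"}[k]


def extract_cell(tile: AssemblyTile, group: str | None = None,
                 config: PipelineConfig | None = None):
    """Averaged lattice vectors from central -> peripheral A translations.

    Returns (UnitCell, LatticeModel, CellDraft).  The cell is snapped to
    the group constraints (p4: a=b, gamma=90; p3/p6: a=b, gamma=120).
    """
    if len(tile.peripheral_A) < 1:
        raise CollinearVectorsError("no propagated A copies")
    if group is None:
        group = group_from_orders(tile.central_A.axis.order_k,
                                  tile.B_copies[0].axis.order_k
                                  if tile.B_copies else 1)
    origin = tile.central_A.axis.anchor[:2]
    vectors = [p.axis.anchor[:2] - origin for p in tile.peripheral_A]
    means, classes = _direction_classes(vectors)
    if len(means) < 2:
        raise CollinearVectorsError(
            "propagated translations span a single direction")
    order = np.argsort([np.linalg.norm(m) for m in means])
    v1 = means[order[0]]
    cls1 = classes[order[0]]
    gamma_ideal = {"p3": 120.0, "p6": 120.0, "p4": 90.0}.get(group)

    def ccw_angle(u, w):
        ang = math.degrees(math.atan2(u[0] * w[1] - u[1] * w[0],
                                      float(np.dot(u, w))))
        return ang % 360.0

    best = None
    for idx in order[1:]:
        w = means[idx]
        ang = ccw_angle(v1, w)
        if ang > 180.0:          # fold into (0, 180) by flipping the vector
            w = -w
            ang = ang - 180.0
        if ang < 1e-6 or ang > 180.0 - 1e-6:
            continue
        if gamma_ideal is not None:
            key = (abs(ang - gamma_ideal), np.linalg.norm(w))
        else:
            key = (np.linalg.norm(w), abs(ang - 90.0))
        if best is None or key < best[0]:
            best = (key, w, idx, ang)
    if best is None:
        raise CollinearVectorsError("no independent second lattice vector")
    _, v2, idx2, gamma_obs = best
    cls2 = classes[idx2]

    a_obs = float(np.mean([np.linalg.norm(v) for v in cls1]))
    b_obs = float(np.mean([np.linalg.norm(v) for v in cls2]))
    if group in ("p3", "p4", "p6"):
        a = b = 0.5 * (a_obs + b_obs)
        gamma = gamma_ideal
    else:
        a, b, gamma = a_obs, b_obs, gamma_obs
    cell = UnitCell(a=a, b=b, gamma=gamma, group=group)

    sg = gemmi.find_spacegroup_by_name(WALLPAPER_SPACEGROUP[group])
    symops = [op.triplet() for op in sg.operations()]
    asym_chain = tile.central_A.model.get_chain(
        tile.central_A.source.chain_order[0]).copy()
    asym = StructureModel([asym_chain], name="asym_unit")
    lattice = LatticeModel(cell=cell, asym_unit=asym, symops=symops)
    draft = CellDraft(v1=v1, v2=v2,
                      lengths_1=[float(np.linalg.norm(v)) for v in cls1],
                      lengths_2=[float(np.linalg.norm(v)) for v in cls2])
    return cell, lattice, draft


def check_termination(tile: AssemblyTile, cell_draft: CellDraft | None,
                      config: PipelineConfig | None = None):
    """Reason codes for the published stop conditions (empty list = ok)."""
    cfg = config or PipelineConfig()
    reasons = []
    tilts = tile.tilt_angles()
    if tilts and max(tilts) > cfg.tilt_max + 1e-6:
        reasons.append("tilt")
    if any(r > cfg.gap_max for r in tile.overlap_rmsds):
        reasons.append("gap")
    if cell_draft is not None:
        a_ideal = float(np.mean(cell_draft.lengths_1))
        b_ideal = float(np.mean(cell_draft.lengths_2))
        devs = ([abs(l - a_ideal) / a_ideal for l in cell_draft.lengths_1]
                + [abs(l - b_ideal) / b_ideal for l in cell_draft.lengths_2])
        if devs and max(devs) > cfg.cell_dev_max:
            reasons.append("lattice_deviation")
    if monomer_rigidity(tile) > cfg.rigid_max:
        reasons.append("not_rigid")
    return reasons


# ---------------------------------------------------------------------------
# mmCIF output
# ---------------------------------------------------------------------------

def emit_lattice(lattice: LatticeModel, path) -> Path:
    """Write the primitive unit cell with explicit symmetry operators.

    The 2D cell is embedded in a 3D crystallographic cell with
    c = 500 A, alpha = beta = 90 deg; every operator leaves z unchanged.
    """
    from .io import _to_gemmi
    path = Path(path)
    st = _to_gemmi(lattice.asym_unit)
    st.cell = gemmi.UnitCell(lattice.cell.a, lattice.cell.b, CELL_C,
                             90.0, 90.0, lattice.cell.gamma)
    st.spacegroup_hm = WALLPAPER_SPACEGROUP[lattice.cell.group]
    doc = st.make_mmcif_document()
    block = doc.sole_block()
    loop = block.init_loop("_space_group_symop.", ["id", "operation_xyz"])
    for i, op in enumerate(lattice.symops, start=1):
        loop.add_row([str(i), gemmi.cif.quote(op)])
    doc.write_file(str(path))
    return path


def read_lattice(path) -> LatticeModel:
    """Re-read an emitted unit-cell mmCIF (cell, group, operators, asym)."""
    from .io import read_structure
    path = Path(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    cell3d = st.cell
    hm = st.spacegroup_hm
    group = {v: k for k, v in WALLPAPER_SPACEGROUP.items()}.get(hm)
    if group is None:
        raise ValueError(f"{path}: unrecognised space group {hm!r}")
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    symops = [s.strip("'\" ") for s in
              block.find_loop("_space_group_symop.operation_xyz")]
    if not symops:
        sg = gemmi.find_spacegroup_by_name(hm)
        symops = [op.triplet() for op in sg.operations()]
    asym = read_structure(path, fmt="mmcif")
    cell = UnitCell(a=cell3d.a, b=cell3d.b, gamma=cell3d.gamma, group=group)
    return LatticeModel(cell=cell, asym_unit=asym, symops=symops)


def expand_lattice(lattice: LatticeModel, n_cells: int = 1) -> StructureModel:
    """Apply operators plus lattice translations to the asymmetric unit.

    Produces the patch of (2*n_cells+1)^2 cells; used to verify that the
    emitted description regenerates the assembled tile.
    """
    cell = gemmi.UnitCell(lattice.cell.a, lattice.cell.b, CELL_C,
                          90.0, 90.0, lattice.cell.gamma)
    ops = [gemmi.Op(op) for op in lattice.symops]
    out = StructureModel(name="expanded")
    counter = 0
    base = lattice.asym_unit
    for op in ops:
        for di in range(-n_cells, n_cells + 1):
            for dj in range(-n_cells, n_cells + 1):
                for ch in base.chains:
                    dup = ch.copy()
                    coords = np.empty_like(dup.coords)
                    for i, xyz in enumerate(dup.coords):
                        f = cell.fractionalize(gemmi.Position(*xyz))
                        fx, fy, fz = op.apply_to_xyz([f.x, f.y, f.z])
                        p = cell.orthogonalize(
                            gemmi.Fractional(fx + di, fy + dj, fz))
                        coords[i] = [p.x, p.y, p.z]
                    dup.coords = coords
                    dup.chain_id = f"{chr(65 + counter % 26)}{counter // 26}"
                    counter += 1
                    out.add_chain(dup)
    return out


# ---------------------------------------------------------------------------
# p1 and capsid variants
# ---------------------------------------------------------------------------

def assemble_p1(full_model: StructureModel, heterodimers,
                config: PipelineConfig | None = None):
    """p1 layer from full-length/single-domain heterodimer interactions.

    `heterodimers` is a list of (model, score_entry, domain_interval)
    with chain order (full-length, bound single domain).  Each strong
    interaction yields the translation that superposes the full-length
    model onto the bound domain; two independent translations define the
    oblique cell.
    """
    cfg = config or PipelineConfig()
    full_chain = full_model.chains[0]
    ca_full = full_chain.ca_coords()
    vectors = []
    for model, score, (dstart, dend) in heterodimers:
        if score.combined < cfg.min_score_symmetry:
            continue
        bound = model.chains[1]
        index = {rid: i for i, rid in enumerate(bound.res_ids)}
        a_pts, b_pts = [], []
        ca_bound = bound.ca_coords()
        for i, rid in enumerate(full_chain.res_ids):
            if dstart <= rid <= dend and rid in index:
                a = ca_full[i]
                b = ca_bound[index[rid]]
                if np.all(np.isfinite(a)) and np.all(np.isfinite(b)):
                    a_pts.append(a)
                    b_pts.append(b)
        if len(a_pts) < 3:
            continue
        tf, rmsd = kabsch(np.array(a_pts), np.array(b_pts))
        if rmsd > cfg.gap_max:
            continue
        centroid = full_model.centroid()
        v = (tf.apply(centroid) - centroid)[:2]
        vectors.append((score.combined, v))
    if len(vectors) < 2:
        raise P1InsufficientError(
            f"{len(vectors)} strong heterodimer interaction(s); need 2")
    vectors.sort(key=lambda sv: -sv[0])
    v1 = vectors[0][1]
    v2 = None
    for _, v in vectors[1:]:
        sin = abs(v1[0] * v[1] - v1[1] * v[0]) / (
            np.linalg.norm(v1) * np.linalg.norm(v))
        if sin > math.sin(math.radians(10.0)):
            v2 = v
            break
    if v2 is None:
        raise DegenerateCellError("all strong translations are collinear")
    gamma = math.degrees(math.atan2(v1[0] * v2[1] - v1[1] * v2[0],
                                    float(np.dot(v1, v2)))) % 360.0
    if gamma > 180.0:
        v2 = -v2
        gamma = gamma - 180.0
    cell = UnitCell(a=float(np.linalg.norm(v1)), b=float(np.linalg.norm(v2)),
                    gamma=gamma, group="p1")
    asym = StructureModel([full_model.chains[0].copy()], name="asym_unit")
    return LatticeModel(cell=cell, asym_unit=asym, symops=["x,y,z"])


def assemble_capsid_tile(complex_A: SymmetryComplex,
                         complex_B: SymmetryComplex, shared_res,
                         config: PipelineConfig | None = None) -> AssemblyTile:
    """Curved tile: B copies placed without axis re-parallelisation.

    The B axes keep their superposed orientation; the tilt angles carry
    the curvature (for an icosahedral vertex/face pair, ~37.4 deg).  No
    closure of the full shell is attempted.
    """
    cfg = config or PipelineConfig()
    if complex_A.axis.order_k < complex_B.axis.order_k:
        complex_A, complex_B = complex_B, complex_A
    tile = AssemblyTile(central_A=align_axis_to_z(complex_A))
    return place_B_copies(tile, complex_B, shared_res, realign=False,
                          config=cfg)


# ---------------------------------------------------------------------------
# layer driver
# ---------------------------------------------------------------------------

@dataclass
class AssemblyResult:
    tile: AssemblyTile
    scores: QualityScores
    cell: UnitCell | None
    lattice: LatticeModel | None
    termination: list[str]

    @property
    def ok(self) -> bool:
        return not self.termination and self.lattice is not None


def assemble_pair(complex_A: SymmetryComplex, complex_B: SymmetryComplex,
                  shared_res, pivot_res=None,
                  extra_B: list[SymmetryComplex] | None = None,
                  config: PipelineConfig | None = None) -> AssemblyResult:
    """Full layer assembly of one axis pair (A = higher order, central).

    `extra_B` supplies complexes from further clusters; they are drawn
    in when the propagated translations of the first pair span only one
    direction (two 2-fold axes generate a 1D repeat, so a p2 lattice
    needs a third axis cluster for its second cell vector).
    """
    cfg = config or PipelineConfig()
    if complex_A.axis.order_k < complex_B.axis.order_k:
        complex_A, complex_B = complex_B, complex_A
    tile = AssemblyTile(central_A=align_axis_to_z(complex_A))
    place_B_copies(tile, complex_B, shared_res, pivot_res=pivot_res,
                   config=cfg)
    propagate_A(tile, shared_res, config=cfg)
    group = group_from_orders(complex_A.axis.order_k,
                              complex_B.axis.order_k)
    cell = lattice = draft = None
    pending = list(extra_B or [])
    while True:
        try:
            cell, lattice, draft = extract_cell(tile, group=group, config=cfg)
            break
        except CollinearVectorsError:
            if not pending:
                break
            nxt = pending.pop(0)
            place_B_copies(tile, nxt, shared_res, pivot_res=pivot_res,
                           config=cfg)
            propagate_A(tile, shared_res, config=cfg)
            group = group_from_orders(
                max(complex_A.axis.order_k, nxt.axis.order_k),
                complex_B.axis.order_k)
    scores = score_tile(tile, cfg)
    termination = check_termination(tile, draft, cfg)
    if lattice is None:
        termination.append("collinear_lattice")
    else:
        lattice.scores = scores
    return AssemblyResult(tile=tile, scores=scores, cell=cell,
                          lattice=lattice, termination=termination)
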