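"""Synthetic structure generator for the lattice-assembly pipeline.

Stands in for a complex-structure predictor at desk scale: rigid
pseudo-protein monomers (three-helix bundles joined by extended linkers)
are placed around k-fold axes, into planted wallpaper lattices with
known cell constants, or onto an icosahedral shell, and emitted together
with score sidecars and a ground-truth record.  All geometry is
deterministic for a fixed seed; Gaussian coordinate noise of chosen
sigma emulates prediction scatter.

The fixtures are geometric, not energetic: helices carry ideal backbone
dihedrals (so hydrogen-bond-based secondary-structure assignment labels
them H), interface spacings are tuned numerically so that ring
neighbours touch below the contact cutoff without steric clashes, and
linkers are smooth coil paths rather than refined loops.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .io import (ScoreEntry, ScoredOligomer, combine_scores, write_scores,
                 write_structure, ScoreSidecar)
from .structure import AtomRecord, Chain, StructureModel

# backbone geometry (A, deg)
_BOND_N_CA, _BOND_CA_C, _BOND_C_N, _BOND_C_O, _BOND_CA_CB = \
    1.458, 1.525, 1.329, 1.231, 1.530
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA, _ANG_CA_C_O = 111.2, 116.2, 121.7, 120.8
_HELIX_PHI, _HELIX_PSI = -57.0, -47.0

CONTACT_TARGET = 4.2   # A; tuned ring separation: touching but clash-free


# ---------------------------------------------------------------------------
# backbone construction
# ---------------------------------------------------------------------------

def _place(a, b, c, bond: float, angle_deg: float, dihedral_deg: float):
    """NeRF atom placement: d with given bond, angle(b,c,d), dihedral."""
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    return c + bond * (-math.cos(ang) * bc
                       + math.sin(ang) * (math.cos(dih) * m
                                          + math.sin(dih) * n))


def _backbone_chain(phis, psis, with_cb=True):
    """Residues [(name, element, coord), ...] from a dihedral sequence."""
    n = len(phis)
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_BOND_N_CA, 0.0, 0.0])]
    ang = math.radians(_ANG_N_CA_C)
    C = [CA[0] + _BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])]
    for i in range(1, n):
        N.append(_place(N[i - 1], CA[i - 1], C[i - 1],
                        _BOND_C_N, _ANG_CA_C_N, psis[i - 1]))
        CA.append(_place(CA[i - 1], C[i - 1], N[i],
                         _BOND_N_CA, _ANG_C_N_CA, 180.0))
        C.append(_place(C[i - 1], N[i], CA[i],
                        _BOND_CA_C, _ANG_N_CA_C, phis[i]))
    residues = []
    for i in range(n):
        atoms = [("N", "N", N[i]), ("CA", "C", CA[i]), ("C", "C", C[i])]
        atoms.append(("O", "O", _place(N[i], CA[i], C[i],
                                       _BOND_C_O, _ANG_CA_C_O,
                                       psis[i] + 180.0)))
        if with_cb:
            atoms.append(("CB", "C", _place(C[i], N[i], CA[i],
                                            _BOND_CA_CB, 110.1, 122.6)))
        residues.append(atoms)
    return residues


def _residue_coords(residues):
    return np.array([c for res in residues for (_, _, c) in res])


def _transform_residues(residues, R, t):
    return [[(n, e, R @ c + t) for (n, e, c) in res] for res in residues]


def ideal_helix(n: int):
    """Alpha-helical residues with the axis along +z, start near origin."""
    residues = _backbone_chain([_HELIX_PHI] * n, [_HELIX_PSI] * n)
    ca = np.array([res[1][2] for res in residues])
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    v = np.cross(axis, [0.0, 0.0, 1.0])
    s = np.linalg.norm(v)
    if s > 1e-9:
        c = float(axis @ [0.0, 0.0, 1.0])
        R = Rotation.from_rotvec(v / s * math.atan2(s, c)).as_matrix()
    else:
        R = np.eye(3)
    residues = _transform_residues(residues, R, np.zeros(3))
    center = _residue_coords(residues).mean(axis=0)
    return _transform_residues(residues, np.eye(3), -center)


def extended_strand(n: int):
    """Beta-extended residues (phi=-120, psi=130)."""
    return _backbone_chain([-120.0] * n, [130.0] * n)


def _strand_backbone_arrays(residues):
    """N, H, C, O arrays of a strand (H rebuilt from the peptide plane)."""
    N = np.array([r[0][2] for r in residues])
    C = np.array([r[2][2] for r in residues])
    O = np.array([r[3][2] for r in residues])
    H = np.full_like(N, np.nan)
    for i in range(1, len(residues)):
        d = C[i - 1] - O[i - 1]
        H[i] = N[i] + d / np.linalg.norm(d)
    return N, H, C, O


def _hbond_count(don, acc) -> int:
    """Inter-strand H-bonds under the electrostatic criterion."""
    Nd, Hd, _, _ = don
    _, _, Ca, Oa = acc
    count = 0
    q = 0.084 * 332.0
    for i in range(len(Nd)):
        if not np.all(np.isfinite(Hd[i])):
            continue
        for j in range(len(Ca)):
            r_on = np.linalg.norm(Nd[i] - Oa[j])
            if r_on > 5.2:
                continue
            e = q * (1.0 / r_on
                     + 1.0 / np.linalg.norm(Hd[i] - Ca[j])
                     - 1.0 / np.linalg.norm(Hd[i] - Oa[j])
                     - 1.0 / np.linalg.norm(Nd[i] - Ca[j]))
            if e < -0.5:
                count += 1
    return count


def _paired_strand_placement(n: int):
    """Rigid placement of a second, flipped strand maximising H-bonds.

    Grid-scans the inter-strand offset (and the two 180-degree flips)
    for the extended-strand template; deterministic.
    """
    res1 = extended_strand(n)
    arr1 = _strand_backbone_arrays(res1)
    flips = {
        "y": Rotation.from_rotvec([0.0, math.pi, 0.0]).as_matrix(),
        "z": Rotation.from_rotvec([0.0, 0.0, math.pi]).as_matrix(),
    }
    center = _residue_coords(res1).mean(axis=0)
    best = None
    for fname, R in flips.items():
        for dy in np.arange(3.8, 5.8, 0.2):
            for dx in np.arange(-3.5, 3.6, 0.5):
                for dz in np.arange(-1.5, 1.6, 0.5):
                    t = center - R @ center + np.array([dx, dy, dz])
                    arr2 = tuple(a @ R.T + t if np.ndim(a) == 2 else a
                                 for a in arr1)
                    # H must be rebuilt in the new frame: rigid, so rotate
                    score = (_hbond_count(arr2, arr1)
                             + _hbond_count(arr1, arr2))
                    if best is None or score > best[0]:
                        best = (score, R, t)
    return res1, best[1], best[2], best[0]


def antiparallel_sheet(n: int = 8):
    """Two-strand antiparallel beta sheet with real H-bond geometry."""
    res1, R, t, _ = _paired_strand_placement(n)
    res2 = _transform_residues(res1, R, t)
    model = StructureModel(name=f"sheet_{n}")
    model.add_chain(_chain_from_residues("A", res1))
    model.add_chain(_chain_from_residues("B", res2))
    return model


def beta_hairpin(n: int = 8):
    """One chain: two H-bonded strands joined by a coil turn."""
    res1, R, t, _ = _paired_strand_placement(n)
    res2 = _transform_residues(res1, R, t)
    turn = _coil_path(res1[-1][2][2], res2[0][0][2], 3, lift=4.0)
    model = StructureModel(name=f"hairpin_{n}")
    model.add_chain(_chain_from_residues("A", res1 + turn + res2))
    return model


def _coil_path(start, end, n, lift=3.0, lift_dir=None):
    """Synthetic coil residues along an arched path from start to end.

    Backbone positions are fabricated around interpolated CA sites; the
    residues are meant to read as coil, not to satisfy bond geometry.
    The arch rises along `lift_dir` (default: the +z component normal to
    the path) to clear the flanking secondary structure.
    """
    start, end = np.asarray(start, float), np.asarray(end, float)
    d = end - start
    length = np.linalg.norm(d)
    u = d / max(length, 1e-9)
    if lift_dir is None:
        perp = np.array([0.0, 0.0, 1.0]) - u[2] * u
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, [0.0, 1.0, 0.0])
    else:
        perp = np.asarray(lift_dir, float)
    perp /= np.linalg.norm(perp)
    residues = []
    for i in range(n):
        f = (i + 1) / (n + 1)
        ca = start + f * d + lift * math.sin(math.pi * f) * perp
        residues.append([
            ("N", "N", ca - 0.7 * u + 0.5 * perp),
            ("CA", "C", ca),
            ("C", "C", ca + 0.7 * u + 0.5 * perp),
            ("O", "O", ca + 0.9 * u - 0.7 * perp),
        ])
    return residues


def helical_bundle(n_res: int, n_helix: int = 3, spacing: float = 8.0):
    """A compact up-down helical bundle of `n_res` residues.

    Helices run along +/-z at the corners of a regular polygon of
    circumradius `spacing`/(2 sin(pi/n_helix)); 4-residue coil stretches
    connect consecutive helices.
    """
    loop_n = 4
    h = (n_res - loop_n * (n_helix - 1)) // n_helix
    extra = n_res - loop_n * (n_helix - 1) - h * n_helix
    lengths = [h + (1 if i < extra else 0) for i in range(n_helix)]
    radius = spacing / (2.0 * math.sin(math.pi / n_helix)) if n_helix > 1 else 0.0
    placed_helices = []
    for i, hl in enumerate(lengths):
        res = ideal_helix(hl)
        if i % 2 == 1:   # antiparallel: flip along z
            R = Rotation.from_rotvec([math.pi, 0.0, 0.0]).as_matrix()
            res = _transform_residues(res, R, np.zeros(3))
        ang = 2.0 * math.pi * i / n_helix
        t = np.array([radius * math.cos(ang), radius * math.sin(ang), 0.0])
        placed_helices.append(_transform_residues(res, np.eye(3), t))
    residues = []
    for i, helix in enumerate(placed_helices):
        residues.extend(helix)
        if i + 1 < len(placed_helices):
            last_c = helix[-1][2][2]
            next_n = placed_helices[i + 1][0][0][2]
            sign = 1.0 if i % 2 == 0 else -1.0
            lift = np.array([0.0, 0.0, sign * 4.0])
            residues.extend(_coil_path(last_c + lift * 0.5,
                                       next_n + lift * 0.5, loop_n,
                                       lift=3.0, lift_dir=lift))
    center = _residue_coords(residues).mean(axis=0)
    return _transform_residues(residues, np.eye(3), -center)


def _chain_from_residues(chain_id: str, residues, start_id: int = 1,
                         res_name: str = "ALA") -> Chain:
    ch = Chain(chain_id)
    for i, atoms in enumerate(residues):
        ch.add_residue(start_id + i, res_name,
                       [AtomRecord(n, e, c) for (n, e, c) in atoms])
    return ch


# ---------------------------------------------------------------------------
# monomers
# ---------------------------------------------------------------------------

def make_monomer(n_domains: int, residues_per_domain: int = 50,
                 seed: int = 0, linker_len: int = 12,
                 domain_gap: float = 16.0) -> StructureModel:
    """Multi-domain pseudo-protein: compact bundles on extended linkers.

    Domains are separated by at least `domain_gap` A of empty space so a
    contact-based separator can recover them; a small seeded jitter
    (0.05 A) decorrelates repeated builds without moving any contact.
    """
    if n_domains < 1:
        raise ValueError("need at least one domain")
    rng = np.random.default_rng(seed)
    residues = []
    x = 0.0
    prev_half = 0.0
    for d in range(n_domains):
        bundle = helical_bundle(residues_per_domain)
        coords = _residue_coords(bundle)
        half = float(np.abs(coords[:, 0]).max())
        if d > 0:
            x += prev_half + domain_gap + half
            entry = np.array([x, 0.0, 0.0]) + bundle[0][0][2]
            exit_ = residues[-1][2][2]
            residues.extend(_coil_path(exit_, entry, linker_len, lift=5.0))
        residues.extend(_transform_residues(bundle, np.eye(3),
                                            np.array([x, 0.0, 0.0])))
        prev_half = half
    jitter = rng.normal(scale=0.05, size=(len(_residue_coords(residues)), 3))
    flat = _residue_coords(residues) + jitter
    out, k = [], 0
    for res in residues:
        out.append([(n, e, flat[k + i]) for i, (n, e, _) in enumerate(res)])
        k += len(res)
    model = StructureModel(name=f"monomer_d{n_domains}_s{seed}")
    model.add_chain(_chain_from_residues("A", out))
    return model


def monomer_domain_intervals(n_domains: int, residues_per_domain: int,
                             linker_len: int = 12):
    """Ground-truth [start, end] residue intervals of make_monomer."""
    intervals = []
    start = 1
    for d in range(n_domains):
        end = start + residues_per_domain - 1
        intervals.append((start, end))
        start = end + 1 + linker_len
    return intervals


# ---------------------------------------------------------------------------
# oligomers around one axis
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """What the generator planted; reproducible from the seed."""

    group: str = "none"            # wallpaper group, "capsid", or "none"
    a: float = 0.0
    b: float = 0.0
    gamma: float = 0.0
    orders: tuple = (0, 0)
    noise_sigma: float = 0.0
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def _rotation_about_axis(direction, angle_deg: float,
                         anchor=np.zeros(3)):
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    R = Rotation.from_rotvec(np.radians(angle_deg) * d).as_matrix()
    t = anchor - R @ anchor
    return R, t


def _min_interdist(coords_a, coords_b) -> float:
    d, _ = cKDTree(coords_b).query(coords_a, k=1)
    return float(d.min())


def _tune_ring_radius(domain_coords, k: int, axis=np.array([0.0, 0.0, 1.0]),
                      anchor=np.zeros(3), target: float = CONTACT_TARGET,
                      lo: float = 2.0, hi: float = 300.0,
                      offset_dir=np.array([1.0, 0.0, 0.0])) -> float:
    """Radius at which adjacent ring copies sit `target` A apart.

    The domain (centred coordinates) is placed at anchor + r*offset_dir
    and rotated about the axis; the gap between neighbouring copies
    grows monotonically with r, so bisection converges.
    """
    coords = domain_coords - domain_coords.mean(axis=0)
    R, t = _rotation_about_axis(axis, 360.0 / k, anchor)

    def gap(r):
        c0 = coords + anchor + r * offset_dir
        c1 = c0 @ R.T + t
        return _min_interdist(c0, c1) - target

    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if gap(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _model_from_copies(name: str, base_residues, transforms,
                       noise_sigma: float, rng) -> StructureModel:
    model = StructureModel(name=name)
    for i, (R, t) in enumerate(transforms):
        res = _transform_residues(base_residues, R, t)
        if noise_sigma > 0:
            flat = _residue_coords(res)
            flat = flat + rng.normal(scale=noise_sigma, size=flat.shape)
            k = 0
            noisy = []
            for r in res:
                noisy.append([(n, e, flat[k + j])
                              for j, (n, e, _) in enumerate(r)])
                k += len(r)
            res = noisy
        model.add_chain(_chain_from_residues(chr(65 + i), res))
    return model


def _residues_of_model(model: StructureModel, chain_id: str = "A"):
    ch = model.get_chain(chain_id)
    res = []
    atom_res = ch.atom_res
    for ri in range(ch.n_res):
        idx = np.nonzero(atom_res == ri)[0]
        res.append([(ch.atom_names[i], ch.elements[i], ch.coords[i])
                    for i in idx])
    return res


def make_oligomer(monomer: StructureModel, k: int, m: int | None = None,
                  radius: float | None = None, noise_sigma: float = 0.0,
                  screw: float = 0.0, seed: int = 0,
                  iptm: float = 0.9, ptm: float = 0.8, relaxed: bool = True,
                  name: str | None = None):
    """m copies of a monomer on a k-fold axis along z.

    Copies sit at angles i*360/k (i < m), centred `radius` A from the
    axis (tuned for ring contact when omitted), with `screw` A of
    translation along z per step and Gaussian noise of `noise_sigma` A
    per atom.  Returns (ScoredOligomer, GroundTruth).
    """
    m = k if m is None else m
    if not (2 <= m <= k <= 6):
        raise ValueError("need 2 <= m <= k <= 6")
    base = _residues_of_model(monomer)
    coords = _residue_coords(base)
    centred = _transform_residues(base, np.eye(3), -coords.mean(axis=0))
    if radius is None:
        radius = _tune_ring_radius(_residue_coords(centred), k)
    rng = np.random.default_rng(seed)
    transforms = []
    for i in range(m):
        R, t = _rotation_about_axis([0, 0, 1], i * 360.0 / k)
        t = t + np.array([0.0, 0.0, i * screw])
        shift = R @ np.array([radius, 0.0, 0.0])
        transforms.append((R, t + shift))
    name = name or f"oligomer_k{k}_m{m}_s{seed}"
    model = _model_from_copies(name, centred, transforms, noise_sigma, rng)
    score = ScoreEntry(combined=combine_scores(iptm, ptm), iptm=iptm,
                       ptm=ptm, relaxed=relaxed)
    olig = ScoredOligomer(model=model, score=score, subchain_id="full")
    truth = GroundTruth(group="none", orders=(k, 0), noise_sigma=noise_sigma,
                        seed=seed, extras={"m": m, "radius": radius,
                                           "screw": screw})
    return olig, truth


# ---------------------------------------------------------------------------
# planted wallpaper lattices
# ---------------------------------------------------------------------------

_GROUP_DEFAULTS = {
    # group: (a, b, gamma, k_A, k_B)
    "p2": (80.0, 95.0, 90.0, 2, 2),
    "p3": (90.0, 90.0, 120.0, 3, 3),
    "p4": (100.0, 100.0, 90.0, 4, 4),
    "p6": (170.0, 170.0, 120.0, 6, 3),
}


@dataclass
class LatticePairFixture:
    """A planted lattice cut into the complexes the pipeline expects."""

    group: str
    monomer: StructureModel
    complex_A: ScoredOligomer
    complexes_B: list[ScoredOligomer]
    truth: GroundTruth
    shared_res: list[int]
    domain_intervals: list[tuple[int, int]]
    heterodimers: list = field(default_factory=list)   # p1 route only

    def write(self, out_dir) -> Path:
        """Emit mmCIF models + score sidecar + ground truth to a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sidecar = ScoreSidecar()
        write_structure(self.monomer, out / "monomer.cif")
        oligs = [self.complex_A] if self.complex_A is not None else []
        for olig in oligs + list(self.complexes_B):
            write_structure(olig.model, out / f"{olig.model.name}.cif")
            sidecar.entries[olig.model.name] = olig.score
        for model, score, interval in self.heterodimers:
            write_structure(model, out / f"{model.name}.cif")
            sidecar.entries[model.name] = score
        write_scores(sidecar, out / "scores.json")
        (out / "ground_truth.json").write_text(self.truth.to_json())
        return out


def _lattice_vectors(a: float, b: float, gamma: float):
    g = math.radians(gamma)
    return (np.array([a, 0.0, 0.0]),
            np.array([b * math.cos(g), b * math.sin(g), 0.0]))


def _star_transforms(k: int, anchor):
    return [_rotation_about_axis([0, 0, 1], i * 360.0 / k, np.asarray(anchor))
            for i in range(k)]


def make_lattice_pair(group: str, a: float | None = None,
                      b: float | None = None, gamma: float | None = None,
                      noise_sigma: float = 0.0, seed: int = 0,
                      residues_per_domain: int = 44,
                      score_A=(0.85, 0.80), score_B=(0.78, 0.80),
                      ) -> LatticePairFixture:
    """Planted wallpaper lattice cut into axis complexes A and B.

    The asymmetric unit is a single two-domain monomer bridging the
    A axis (at the origin) and the nearest B axis; complex A consists of
    the k_A rotation images around the origin, complex B of the k_B
    images around the B-axis position.  Both complexes share the
    identity monomer, exactly as overlap superposition expects.  For p2,
    whose two-axis pairs only generate a 1D repeat, a second B-type
    complex on an independent 2-fold axis is emitted as well.
    """
    if group == "p1":
        return _make_p1_fixture(a, b, gamma, noise_sigma, seed,
                                residues_per_domain)
    if group not in _GROUP_DEFAULTS:
        raise ValueError(f"unsupported group {group!r}")
    da, db, dg, k_A, k_B = _GROUP_DEFAULTS[group]
    a = da if a is None else a
    b = a if group in ("p3", "p4", "p6") else (db if b is None else b)
    gamma = dg if gamma is None else gamma
    v1, v2 = _lattice_vectors(a, b, gamma)
    if group in ("p3", "p6"):
        centers_B = [v1 / 3.0 + 2.0 * v2 / 3.0]
    elif group == "p4":
        centers_B = [0.5 * (v1 + v2)]
    else:   # p2: two independent 2-fold classes
        centers_B = [0.5 * v1, 0.5 * v2]

    rng = np.random.default_rng(seed)
    linker_len = 14
    bundle = helical_bundle(residues_per_domain)
    bcoords = _residue_coords(bundle)

    # one interface domain per axis the monomer participates in: the
    # A axis at the origin plus every listed B-axis position
    e0 = centers_B[0] / np.linalg.norm(centers_B[0])
    r_A = _tune_ring_radius(bcoords, k_A, offset_dir=e0)
    dom_positions = [r_A * e0]
    for c in centers_B:
        e = c / np.linalg.norm(c)
        r = _tune_ring_radius(bcoords, k_B, anchor=c, offset_dir=-e)
        dom_positions.append(c - r * e)
    doms = [_transform_residues(bundle, np.eye(3), p) for p in dom_positions]
    monomer_res = list(doms[0])
    domain_intervals = [(1, residues_per_domain)]
    cursor = residues_per_domain
    for d in doms[1:]:
        exit_ = monomer_res[-1][2][2]
        monomer_res.extend(_coil_path(exit_, d[0][0][2], linker_len, lift=6.0))
        cursor += linker_len
        monomer_res.extend(d)
        domain_intervals.append((cursor + 1, cursor + residues_per_domain))
        cursor += residues_per_domain
    jitter = rng.normal(scale=0.05, size=(len(_residue_coords(monomer_res)), 3))
    flat = _residue_coords(monomer_res) + jitter
    out_res, kk = [], 0
    for res in monomer_res:
        out_res.append([(n, el, flat[kk + i])
                        for i, (n, el, _) in enumerate(res)])
        kk += len(res)
    monomer_res = out_res
    monomer = StructureModel(name=f"{group}_monomer_s{seed}")
    monomer.add_chain(_chain_from_residues("A", monomer_res))
    n_res = len(monomer_res)

    iptm_A, ptm_A = score_A
    iptm_B, ptm_B = score_B
    complex_A = _model_from_copies(f"{group}_axisA_s{seed}", monomer_res,
                                   _star_transforms(k_A, np.zeros(3)),
                                   noise_sigma, rng)
    olig_A = ScoredOligomer(
        model=complex_A,
        score=ScoreEntry(combined=combine_scores(iptm_A, ptm_A),
                         iptm=iptm_A, ptm=ptm_A))
    oligs_B = []
    for bi, center in enumerate(centers_B):
        tag = "" if len(centers_B) == 1 else str(bi + 1)
        model_B = _model_from_copies(f"{group}_axisB{tag}_s{seed}",
                                     monomer_res,
                                     _star_transforms(k_B, center),
                                     noise_sigma, rng)
        oligs_B.append(ScoredOligomer(
            model=model_B,
            score=ScoreEntry(combined=combine_scores(iptm_B, ptm_B),
                             iptm=iptm_B, ptm=ptm_B)))
    truth = GroundTruth(group=group, a=a, b=b, gamma=gamma,
                        orders=(k_A, k_B), noise_sigma=noise_sigma,
                        seed=seed,
                        extras={"centers_B": [list(c) for c in centers_B]})
    return LatticePairFixture(
        group=group, monomer=monomer, complex_A=olig_A, complexes_B=oligs_B,
        truth=truth, shared_res=list(range(1, n_res + 1)),
        domain_intervals=domain_intervals)


def _tune_approach(fixed_coords, move_coords, direction,
                   target: float = CONTACT_TARGET,
                   lo: float = 0.0, hi: float | None = None):
    """Distance t along `direction` placing move+t*u `target` A from fixed.

    The gap shrinks monotonically as t grows towards the fixed body, so
    bisection converges on the touching distance.
    """
    direction = np.asarray(direction, float)
    u = direction / np.linalg.norm(direction)
    if hi is None:
        hi = float(np.linalg.norm(direction))

    def gap(t):
        return _min_interdist(move_coords + t * u, fixed_coords) - target

    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if gap(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _make_p1_fixture(a, b, gamma, noise_sigma, seed, residues_per_domain):
    """Oblique p1 layer: full-length monomer + single-domain heterodimers."""
    a = 73.0 if a is None else a
    b = 89.0 if b is None else b
    gamma = 105.0 if gamma is None else gamma
    v1, v2 = _lattice_vectors(a, b, gamma)
    rng = np.random.default_rng(seed)
    linker_len = 12
    bundle = helical_bundle(residues_per_domain)
    bcoords = _residue_coords(bundle)

    # d1 anchors the origin; d2 binds d1 of the +v1 neighbour, d3 of +v2
    pos = [np.zeros(3)]
    for v in (v1, v2):
        t = _tune_approach(bcoords + v, bcoords, v)
        pos.append(t * (v / np.linalg.norm(v)))
    doms = [_transform_residues(bundle, np.eye(3), p) for p in pos]
    monomer_res = list(doms[0])
    intervals = [(1, residues_per_domain)]
    cursor = residues_per_domain
    for d in doms[1:]:
        exit_ = monomer_res[-1][2][2]
        monomer_res.extend(_coil_path(exit_, d[0][0][2], linker_len, lift=6.0))
        cursor += linker_len
        monomer_res.extend(d)
        intervals.append((cursor + 1, cursor + residues_per_domain))
        cursor += residues_per_domain
    jitter = rng.normal(scale=0.05,
                        size=(len(_residue_coords(monomer_res)), 3))
    flat = _residue_coords(monomer_res) + jitter
    out_res, kk = [], 0
    for res in monomer_res:
        out_res.append([(n, el, flat[kk + i])
                        for i, (n, el, _) in enumerate(res)])
        kk += len(res)
    monomer_res = out_res
    monomer = StructureModel(name=f"p1_monomer_s{seed}")
    monomer.add_chain(_chain_from_residues("A", monomer_res))

    d1_interval = intervals[0]
    d1_res = monomer_res[d1_interval[0] - 1:d1_interval[1]]
    heterodimers = []
    for vi, v in enumerate((v1, v2)):
        model = StructureModel(name=f"p1_het{vi + 1}_s{seed}")
        full_chain = _chain_from_residues("A", monomer_res)
        bound = _transform_residues(d1_res, np.eye(3), v)
        if noise_sigma > 0:
            flatb = _residue_coords(bound)
            flatb = flatb + rng.normal(scale=noise_sigma, size=flatb.shape)
            kk = 0
            noisy = []
            for r in bound:
                noisy.append([(n, el, flatb[kk + j])
                              for j, (n, el, _) in enumerate(r)])
                kk += len(r)
            bound = noisy
        model.add_chain(full_chain)
        model.add_chain(_chain_from_residues("B", bound,
                                             start_id=d1_interval[0]))
        score = ScoreEntry(combined=combine_scores(0.8, 0.75),
                           iptm=0.8, ptm=0.75)
        heterodimers.append((model, score, d1_interval))
    truth = GroundTruth(group="p1", a=a, b=b, gamma=gamma, orders=(1, 1),
                        noise_sigma=noise_sigma, seed=seed)
    return LatticePairFixture(
        group="p1", monomer=monomer, complex_A=None, complexes_B=[],
        truth=truth, shared_res=list(range(1, len(monomer_res) + 1)),
        domain_intervals=intervals, heterodimers=heterodimers)


# ---------------------------------------------------------------------------
# capsid patch (icosahedral T=1 vertex + face)
# ---------------------------------------------------------------------------

def _icosahedron(radius: float):
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    raw = []
    for s1 in (-1.0, 1.0):
        for s2 in (-1.0, 1.0):
            raw += [(0.0, s1, s2 * phi), (s1, s2 * phi, 0.0),
                    (s2 * phi, 0.0, s1)]
    verts = np.unique(np.round(np.array(raw), 9), axis=0)
    verts = verts / np.linalg.norm(verts[0]) * radius
    # faces: triangles of mutually nearest vertices
    d = np.linalg.norm(verts[:, None] - verts[None, :], axis=2)
    edge = np.min(d[d > 1e-6])
    faces = []
    n = len(verts)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(d[i, j] - edge) > 1e-6:
                continue
            for k in range(j + 1, n):
                if (abs(d[i, k] - edge) < 1e-6
                        and abs(d[j, k] - edge) < 1e-6):
                    faces.append((i, j, k))
    return verts, faces


def make_capsid_patch(seed: int = 0, radius: float = 60.0,
                      residues_per_domain: int = 40,
                      noise_sigma: float = 0.0):
    """Icosahedral vertex pentamer + adjacent face trimer, one shared
    subunit orientation.

    Returns (pentamer, trimer, GroundTruth); the truth records the
    planted inter-axis angle between the 5-fold vertex axis and the
    3-fold face axis (arccos of the normalized axis dot product,
    ~37.377 deg for an icosahedron).
    """
    verts, faces = _icosahedron(radius)
    # vertex axis: pick the vertex with the largest z
    vi = int(np.argmax(verts[:, 2]))
    v_axis = verts[vi] / np.linalg.norm(verts[vi])
    adj = [f for f in faces if vi in f]
    centers = [verts[list(f)].mean(axis=0) for f in adj]
    f_center = centers[int(np.argmax([c[2] for c in centers]))]
    f_axis = f_center / np.linalg.norm(f_center)
    angle = math.degrees(math.acos(float(np.clip(v_axis @ f_axis, -1, 1))))

    rng = np.random.default_rng(seed)
    bundle = helical_bundle(residues_per_domain)
    bcoords = _residue_coords(bundle)

    def ring_position(axis, k, towards):
        """Ring site offset along the meridian towards the partner axis,
        so the monomer stays inside its own angular wedge."""
        axis = axis / np.linalg.norm(axis)
        u = towards - axis * float(np.dot(towards, axis))
        u /= np.linalg.norm(u)
        anchor = axis * radius * 0.95
        r = _tune_ring_radius(bcoords, k, axis=axis, anchor=anchor,
                              offset_dir=u)
        return anchor + r * u

    pos_v = ring_position(v_axis, 5, f_axis)
    pos_f = ring_position(f_axis, 3, v_axis)
    dom_v = _transform_residues(bundle, np.eye(3), pos_v)
    dom_f = _transform_residues(bundle, np.eye(3), pos_f)
    # arch the linker radially outward so it clears the vertex ring
    outward = 0.5 * (pos_v + pos_f)
    outward /= np.linalg.norm(outward)
    linker = _coil_path(dom_v[-1][2][2], dom_f[0][0][2], 12, lift=9.0,
                        lift_dir=outward)
    monomer_res = dom_v + linker + dom_f
    n_res = len(monomer_res)

    def star(axis, k, name, iptm, ptm):
        transforms = [_rotation_about_axis(axis, i * 360.0 / k)
                      for i in range(k)]
        model = _model_from_copies(name, monomer_res, transforms,
                                   noise_sigma, rng)
        return ScoredOligomer(
            model=model,
            score=ScoreEntry(combined=combine_scores(iptm, ptm),
                             iptm=iptm, ptm=ptm))

    pentamer = star(v_axis, 5, f"capsid_5fold_s{seed}", 0.72, 0.70)
    trimer = star(f_axis, 3, f"capsid_3fold_s{seed}", 0.55, 0.60)
    truth = GroundTruth(group="capsid", orders=(5, 3),
                        noise_sigma=noise_sigma, seed=seed,
                        extras={"inter_axis_angle_deg": angle,
                                "radius": radius, "n_res": n_res})
    return pentamer, trimer, truth
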