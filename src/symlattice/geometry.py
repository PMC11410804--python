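"""Contact and surface primitives shared by the downstream modules."""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.spatial import cKDTree

from .config import vdw_radius
from .structure import Chain, StructureModel


def _gather_atoms(model: StructureModel, selection):
    """Flatten a residue selection into (coords, residue_keys, elements).

    `selection` is an iterable of (chain_id, res_id) pairs; heavy atoms only.
    """
    by_chain: dict[str, set[int]] = {}
    for cid, rid in selection:
        by_chain.setdefault(cid, set()).add(int(rid))
    coords, keys, elements = [], [], []
    for ch in model.chains:
        if ch.chain_id not in by_chain:
            continue
        wanted = by_chain[ch.chain_id]
        heavy = ch.heavy_mask
        res = ch.atom_res
        for i in range(ch.n_atoms):
            if not heavy[i]:
                continue
            rid = ch.res_ids[res[i]]
            if rid in wanted:
                coords.append(ch.coords[i])
                keys.append((ch.chain_id, rid))
                elements.append(ch.elements[i])
    arr = np.array(coords) if coords else np.zeros((0, 3))
    return arr, keys, elements


def chain_selection(chain: Chain):
    return [(chain.chain_id, rid) for rid in chain.res_ids]


def model_selection(model: StructureModel):
    return [(c.chain_id, rid) for c in model.chains for rid in c.res_ids]


def contact_count(model: StructureModel, sel_a, sel_b, cutoff: float) -> int:
    """Number of residue pairs with min heavy-atom distance below `cutoff`.

    Symmetric in the two selections; a residue never pairs with itself.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ca, ka, _ = _gather_atoms(model, sel_a)
    cb, kb, _ = _gather_atoms(model, sel_b)
    if len(ca) == 0 or len(cb) == 0:
        warnings.warn("empty selection in contact_count")
        return 0
    pairs = cKDTree(ca).query_ball_tree(cKDTree(cb), cutoff)
    respairs = set()
    for ia, ibs in enumerate(pairs):
        for ib in ibs:
            if ka[ia] == kb[ib]:
                continue
            respairs.add((min(ka[ia], kb[ib]), max(ka[ia], kb[ib])))
    return len(respairs)


def contact_pairs(model: StructureModel, sel_a, sel_b, cutoff: float):
    """The contacting residue pairs themselves (unordered, deduplicated)."""
    ca, ka, _ = _gather_atoms(model, sel_a)
    cb, kb, _ = _gather_atoms(model, sel_b)
    if len(ca) == 0 or len(cb) == 0:
        return set()
    pairs = cKDTree(ca).query_ball_tree(cKDTree(cb), cutoff)
    out = set()
    for ia, ibs in enumerate(pairs):
        for ib in ibs:
            if ka[ia] != kb[ib]:
                out.add((min(ka[ia], kb[ib]), max(ka[ia], kb[ib])))
    return out


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere sampling."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def surface_area(model: StructureModel, sel, probe: float = 1.4,
                 n_points: int = 240) -> float:
    """Numeric solvent-accessible area (A^2) of a residue selection.

    Shrake-Rupley style: each heavy atom is sampled with a deterministic
    Fibonacci sphere at radius r_vdw + probe; points inside any other
    selected atom's probe-extended sphere are occluded.  The selection is
    treated as an isolated unit.  Unknown elements fall back to the
    default 1.70 A radius with a warning.
    """
    coords, keys, elements = _gather_atoms(model, sel)
    if len(coords) == 0:
        warnings.warn("empty selection in surface_area")
        return 0.0
    from .config import VDW_RADII
    radii = np.empty(len(coords))
    for i, el in enumerate(elements):
        if el.upper() not in VDW_RADII:
            warnings.warn(f"unknown element {el!r}; default radius used")
        radii[i] = vdw_radius(el)
    radii = radii + probe
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    area = 0.0
    rmax = radii.max()
    for i in range(len(coords)):
        pts = coords[i] + radii[i] * sphere
        neigh = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax)
                 if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neigh:
            d = np.linalg.norm(pts - coords[j], axis=1)
            exposed &= d >= radii[j]
        area += 4.0 * math.pi * radii[i] ** 2 * exposed.sum() / n_points
    return float(area)


def min_residue_distances(model: StructureModel, chain_a: Chain,
                          chain_b: Chain, cap: float) -> np.ndarray:
    """(n_res_a, n_res_b) matrix of min heavy-atom distances, capped."""
    out = np.full((chain_a.n_res, chain_b.n_res), cap)
    heavy_a, heavy_b = chain_a.heavy_mask, chain_b.heavy_mask
    ca = chain_a.coords[heavy_a]
    cb = chain_b.coords[heavy_b]
    ra = chain_a.atom_res[heavy_a]
    rb = chain_b.atom_res[heavy_b]
    if len(ca) == 0 or len(cb) == 0:
        return out
    pairs = cKDTree(ca).query_ball_tree(cKDTree(cb), cap)
    for ia, ibs in enumerate(pairs):
        if not ibs:
            continue
        d = np.linalg.norm(cb[ibs] - ca[ia], axis=1)
        for ib, dist in zip(ibs, d):
            if dist < out[ra[ia], rb[ib]]:
                out[ra[ia], rb[ib]] = dist
    return out
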