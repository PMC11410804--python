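"""Secondary-structure assignment from backbone geometry.

Hydrogen bonds are detected with the classic electrostatic criterion:
the amide hydrogen is rebuilt from the preceding peptide plane, the
interaction energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

is evaluated for donor/acceptor pairs, and a bond is called when
E < -0.5 kcal/mol.  Labels are reduced to the three states consumed
downstream: H (alpha-helix, two consecutive i->i+4 turns), E (beta
bridge, parallel or antiparallel ladder geometry), C (everything else).
Beta-bridge partners are recorded on the model so the intermolecular
beta-strand filter can distinguish intra- from inter-chain pairing.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .structure import StructureModel

HB_ENERGY_CUTOFF = -0.5   # kcal/mol
_Q = 0.084 * 332.0        # coupling constant of the electrostatic model
_MAX_ON_DIST = 5.2        # A; pairs beyond this cannot reach the cutoff


def _backbone(model: StructureModel):
    """Per-residue N, CA, C, O and rebuilt H for every chain.

    Returns a list of dicts (one per chain) with (n_res, 3) arrays; NaN
    rows mark missing atoms.  H is placed 1 A from N along the O->C
    direction of the preceding residue (undefined for chain starts and
    prolines would be skipped in a chemistry-aware treatment; fixtures
    carry no proline).
    """
    out = []
    for ch in model.chains:
        n = ch.backbone_coords("N")
        ca = ch.backbone_coords("CA")
        c = ch.backbone_coords("C")
        o = ch.backbone_coords("O")
        h = np.full_like(n, np.nan)
        for i in range(1, ch.n_res):
            # only build H across a real peptide bond (contiguous numbering)
            if ch.res_ids[i] != ch.res_ids[i - 1] + 1:
                continue
            d = c[i - 1] - o[i - 1]
            norm = np.linalg.norm(d)
            if np.all(np.isfinite(d)) and norm > 1e-6 and np.all(np.isfinite(n[i])):
                h[i] = n[i] + d / norm
        out.append({"N": n, "CA": ca, "C": c, "O": o, "H": h})
    return out


def _hbond_matrix(model: StructureModel, bb):
    """Set of (donor, acceptor) residue keys with E < cutoff.

    Keys are (chain_index, residue_index) tuples.
    """
    donors, donor_keys = [], []
    acceptors, acceptor_keys = [], []
    for ci, arrs in enumerate(bb):
        for ri in range(len(arrs["N"])):
            if np.all(np.isfinite(arrs["N"][ri])) and np.all(np.isfinite(arrs["H"][ri])):
                donors.append((arrs["N"][ri], arrs["H"][ri]))
                donor_keys.append((ci, ri))
            if np.all(np.isfinite(arrs["C"][ri])) and np.all(np.isfinite(arrs["O"][ri])):
                acceptors.append((arrs["C"][ri], arrs["O"][ri]))
                acceptor_keys.append((ci, ri))
    bonds = set()
    if not donors or not acceptors:
        return bonds
    d_n = np.array([d[0] for d in donors])
    a_o = np.array([a[1] for a in acceptors])
    tree_d = cKDTree(d_n)
    tree_a = cKDTree(a_o)
    for di, ais in enumerate(tree_d.query_ball_tree(tree_a, _MAX_ON_DIST)):
        nd, hd = donors[di]
        for ai in ais:
            ck, ok = acceptors[ai]
            if donor_keys[di] == acceptor_keys[ai]:
                continue
            # exclude the trivially bonded neighbour (i -> i-1 amide)
            if (donor_keys[di][0] == acceptor_keys[ai][0]
                    and abs(donor_keys[di][1] - acceptor_keys[ai][1]) < 1):
                continue
            r_on = np.linalg.norm(nd - ok)
            r_oh = np.linalg.norm(hd - ok)
            r_cn = np.linalg.norm(nd - ck)
            r_ch = np.linalg.norm(hd - ck)
            if min(r_oh, r_on) < 0.5:
                continue  # degenerate geometry
            e = _Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            if e < HB_ENERGY_CUTOFF:
                bonds.add((donor_keys[di], acceptor_keys[ai]))
    return bonds


def assign_sse(model: StructureModel) -> StructureModel:
    """Label every residue H/E/C in place and record beta-bridge partners.

    Residues lacking backbone atoms are labelled C and counted in
    ``model.sse_warnings``.  Deterministic for fixed input.
    """
    bb = _backbone(model)
    bonds = _hbond_matrix(model, bb)

    def hb(acc, don):
        return (don, acc) in bonds

    labels = [np.array(["C"] * ch.n_res, dtype="<U1") for ch in model.chains]
    warnings = 0
    for ci, ch in enumerate(model.chains):
        arrs = bb[ci]
        for ri in range(ch.n_res):
            if not (np.all(np.isfinite(arrs["N"][ri]))
                    and np.all(np.isfinite(arrs["CA"][ri]))
                    and np.all(np.isfinite(arrs["C"][ri]))):
                warnings += 1

    # alpha helix: turns at i and i+1 (CO_i <- NH_{i+4}) label i+1..i+4
    for ci, ch in enumerate(model.chains):
        nres = ch.n_res
        turn = [hb((ci, i), (ci, i + 4)) for i in range(nres - 4)] + [False] * 4
        for i in range(nres - 5):
            if turn[i] and turn[i + 1]:
                for j in range(i + 1, i + 5):
                    labels[ci][j] = "H"

    # beta bridges: only residue pairs within one step of an H-bond can bridge
    bridges = []
    keyset = {(ci, ri) for ci, ch in enumerate(model.chains)
              for ri in range(ch.n_res)}

    def shift(key, d):
        k = (key[0], key[1] + d)
        return k if k in keyset else None

    candidates = set()
    for don, acc in bonds:
        for da in (-1, 0, 1):
            for db in (-1, 0, 1):
                a = (don[0], don[1] + da)
                b = (acc[0], acc[1] + db)
                if a in keyset and b in keyset and a != b:
                    candidates.add((min(a, b), max(a, b)))

    seen = set()
    for (ci, i), (cj, j) in sorted(candidates):
            if ci == cj and abs(i - j) < 3:
                continue
            a, b = (ci, i), (cj, j)
            am, ap = shift(a, -1), shift(a, 1)
            bm, bp = shift(b, -1), shift(b, 1)
            para = ((am is not None and bp is not None
                     and hb(am, b) and hb(b, ap)) if ap else False) or \
                   ((bm is not None and ap is not None
                     and hb(bm, a) and hb(a, bp)) if bp else False)
            anti = (hb(a, b) and hb(b, a)) or \
                   (am is not None and bp is not None and bm is not None
                    and ap is not None and hb(am, bp) and hb(bm, ap))
            if para or anti:
                if (a, b) in seen:
                    continue
                seen.add((a, b))
                bridges.append((a, b))
                if labels[ci][i] != "H":
                    labels[ci][i] = "E"
                if labels[cj][j] != "H":
                    labels[cj][j] = "E"

    for ci, ch in enumerate(model.chains):
        ch.sse = labels[ci]
    model.bridge_partners = [
        ((model.chains[a[0]].chain_id, model.chains[a[0]].res_ids[a[1]]),
         (model.chains[b[0]].chain_id, model.chains[b[0]].res_ids[b[1]]))
        for a, b in bridges]
    model.sse_warnings = warnings
    return model
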