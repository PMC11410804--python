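"""Hierarchical coordinate container.

A :class:`StructureModel` holds ordered chains; each chain stores its
residues (1-based author numbering, strictly increasing) and a flat atom
table backed by numpy arrays.  This is the universal currency passed
between I/O, secondary-structure assignment, symmetry detection and
assembly.  Geometry code operates on the flat arrays; residue-level
bookkeeping (numbering, per-residue secondary structure) stays explicit
so that truncated subchains can always be mapped back to full-length
numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class AtomRecord:
    """One atom: label, element symbol, coordinate (A), hydrogen flag."""

    name: str
    element: str
    coord: np.ndarray
    is_hydrogen: bool = False

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError("atom coordinate must be a finite 3-vector")


class Chain:
    """One polymer chain: residue metadata plus a flat atom table."""

    def __init__(self, chain_id: str):
        self.chain_id = chain_id
        self.res_ids: list[int] = []          # author numbering, increasing
        self.res_names: list[str] = []
        self._atom_names: list[str] = []
        self._elements: list[str] = []
        self._coords: list[np.ndarray] = []
        self._atom_res: list[int] = []        # per-atom residue index
        self.sse: np.ndarray | None = None    # per-residue {H, E, C}
        self._coord_arr: np.ndarray | None = None

    # -- construction ------------------------------------------------
    def add_residue(self, res_id: int, res_name: str, atoms: list[AtomRecord]):
        if self.res_ids and res_id <= self.res_ids[-1]:
            raise ValueError(
                f"residue numbering must be strictly increasing in chain "
                f"{self.chain_id}: {res_id} after {self.res_ids[-1]}")
        if not any(not a.is_hydrogen for a in atoms):
            raise ValueError(f"residue {res_id} has no heavy atom")
        idx = len(self.res_ids)
        self.res_ids.append(int(res_id))
        self.res_names.append(res_name)
        for a in atoms:
            self._atom_names.append(a.name)
            self._elements.append(a.element)
            self._coords.append(np.asarray(a.coord, dtype=float))
            self._atom_res.append(idx)
        self._coord_arr = None

    # -- views -------------------------------------------------------
    @property
    def n_res(self) -> int:
        return len(self.res_ids)

    @property
    def n_atoms(self) -> int:
        return len(self._atom_names)

    @property
    def coords(self) -> np.ndarray:
        if self._coord_arr is None:
            self._coord_arr = (np.array(self._coords, dtype=float)
                               if self._coords else np.zeros((0, 3)))
        return self._coord_arr

    @coords.setter
    def coords(self, value: np.ndarray):
        value = np.asarray(value, dtype=float)
        if value.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        self._coords = [v for v in value]
        self._coord_arr = value

    @property
    def atom_names(self) -> list[str]:
        return self._atom_names

    @property
    def elements(self) -> list[str]:
        return self._elements

    @property
    def atom_res(self) -> np.ndarray:
        return np.asarray(self._atom_res, dtype=int)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([e.upper() not in ("H", "D") for e in self._elements])

    @property
    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(n, "X") for n in self.res_names)

    def atom_index(self, res_index: int, name: str) -> int | None:
        """Flat index of atom `name` in residue `res_index`, or None."""
        res = self.atom_res
        for i in np.nonzero(res == res_index)[0]:
            if self._atom_names[i] == name:
                return int(i)
        return None

    def backbone_coords(self, name: str) -> np.ndarray:
        """(n_res, 3) coordinates of backbone atom `name`; NaN if absent."""
        out = np.full((self.n_res, 3), np.nan)
        res = self.atom_res
        for i, aname in enumerate(self._atom_names):
            if aname == name:
                out[res[i]] = self.coords[i]
        return out

    def ca_coords(self) -> np.ndarray:
        return self.backbone_coords("CA")

    def res_index_of(self, res_id: int) -> int:
        return self.res_ids.index(int(res_id))

    def atom_mask_for_residues(self, res_ids) -> np.ndarray:
        """Boolean per-atom mask covering the given author residue ids."""
        wanted = set(int(r) for r in res_ids)
        keep = np.array([rid in wanted for rid in self.res_ids])
        return keep[self.atom_res]

    def subset(self, res_ids) -> "Chain":
        """New chain restricted to `res_ids` (author numbering kept)."""
        wanted = sorted(set(int(r) for r in res_ids) & set(self.res_ids))
        ch = Chain(self.chain_id)
        res = self.atom_res
        for rid in wanted:
            ri = self.res_index_of(rid)
            atoms = [AtomRecord(self._atom_names[i], self._elements[i],
                                self.coords[i],
                                self._elements[i].upper() in ("H", "D"))
                     for i in np.nonzero(res == ri)[0]]
            ch.add_residue(rid, self.res_names[ri], atoms)
        if self.sse is not None:
            idx = [self.res_index_of(r) for r in wanted]
            ch.sse = self.sse[idx]
        return ch

    def copy(self) -> "Chain":
        ch = Chain(self.chain_id)
        ch.res_ids = list(self.res_ids)
        ch.res_names = list(self.res_names)
        ch._atom_names = list(self._atom_names)
        ch._elements = list(self._elements)
        ch._coords = [c.copy() for c in self._coords]
        ch._atom_res = list(self._atom_res)
        ch.sse = None if self.sse is None else self.sse.copy()
        return ch


@dataclass
class StructureModel:
    """Ordered chains with coordinates, sequence and SSE labels."""

    chains: list[Chain] = field(default_factory=list)
    name: str = "model"
    # inter-residue beta-bridge partners, set by sse.assign_sse:
    # list of ((chain_id, res_id), (chain_id, res_id))
    bridge_partners: list = field(default_factory=list)
    sse_warnings: int = 0

    def __post_init__(self):
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("chain ids must be unique")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def get_chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    def add_chain(self, chain: Chain):
        if chain.chain_id in self.chain_ids:
            raise ValueError(f"duplicate chain id {chain.chain_id}")
        self.chains.append(chain)

    @property
    def n_atoms(self) -> int:
        return sum(c.n_atoms for c in self.chains)

    @property
    def n_res(self) -> int:
        return sum(c.n_res for c in self.chains)

    def all_coords(self) -> np.ndarray:
        if not self.chains:
            return np.zeros((0, 3))
        return np.vstack([c.coords for c in self.chains])

    def set_all_coords(self, value: np.ndarray):
        value = np.asarray(value, dtype=float)
        off = 0
        for c in self.chains:
            c.coords = value[off:off + c.n_atoms]
            off += c.n_atoms

    def transform(self, rotation: np.ndarray, translation: np.ndarray):
        """Apply x -> R x + t in place."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        for c in self.chains:
            c.coords = c.coords @ R.T + t

    def copy(self) -> "StructureModel":
        m = StructureModel([c.copy() for c in self.chains], name=self.name)
        m.bridge_partners = list(self.bridge_partners)
        m.sse_warnings = self.sse_warnings
        return m

    def centroid(self) -> np.ndarray:
        return self.all_coords().mean(axis=0)
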