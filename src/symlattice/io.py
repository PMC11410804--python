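"""Reading and writing of coordinate files, score sidecars and domain FASTA.

PDB and mmCIF parsing/serialisation is delegated to gemmi; this module
converts between gemmi's hierarchy and the package's
:class:`~symlattice.structure.StructureModel`, preserving author chain ids,
author residue numbering and coordinates.

Score sidecars are JSON files carrying the complex-prediction confidence
metrics per model.  Two dialects are accepted:

* component-wise: ``{"model_1": {"iptm": 0.8, "ptm": 0.7, "relaxed": true}}``
  -- the combined score is computed as ``0.8*iptm + 0.2*ptm``;
* precombined (AlphaFold ranking style): ``{"iptm+ptm": {"model_1": 0.78}}``
  -- values are passed through unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .structure import AtomRecord, Chain, StructureModel

IPTM_WEIGHT = 0.8
PTM_WEIGHT = 0.2


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def _from_gemmi(st: gemmi.Structure, name: str) -> StructureModel:
    if len(st) == 0:
        raise ParseError(f"{name}: no models in file")
    gm = st[0]
    model = StructureModel(name=name)
    for gch in gm:
        ch = Chain(gch.name)
        for res in gch:
            atoms = []
            for at in res:
                el = at.element.name
                atoms.append(AtomRecord(
                    name=at.name, element=el,
                    coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    is_hydrogen=bool(at.element.is_hydrogen)))
            if not atoms or not any(not a.is_hydrogen for a in atoms):
                continue
            ch.add_residue(res.seqid.num, res.name, atoms)
        if ch.n_res:
            model.add_chain(ch)
    if model.n_atoms == 0:
        raise ParseError(f"{name}: structure contains no atoms")
    return model


def read_structure(path, fmt: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel.

    `fmt` is one of {"pdb", "mmcif", "auto"}; "auto" dispatches on the
    file extension.  Hydrogens are retained but flagged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return _from_gemmi(st, path.stem)


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.name
    gm = gemmi.Model("1")
    for ch in model.chains:
        gch = gemmi.Chain(ch.chain_id)
        res_atoms = ch.atom_res
        for ri, (rid, rname) in enumerate(zip(ch.res_ids, ch.res_names)):
            gres = gemmi.Residue()
            gres.name = rname
            gres.seqid = gemmi.SeqId(int(rid), " ")
            for ai in np.nonzero(res_atoms == ri)[0]:
                at = gemmi.Atom()
                at.name = ch.atom_names[ai]
                at.element = gemmi.Element(ch.elements[ai])
                x, y, z = np.round(ch.coords[ai], 3)
                at.pos = gemmi.Position(x, y, z)
                at.occ = 1.0
                at.b_iso = 0.0
                gres.add_atom(at)
            gch.add_residue(gres)
        gm.add_chain(gch)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path, fmt: str = "auto") -> Path:
    """Write a StructureModel as PDB or mmCIF (3-decimal coordinates)."""
    path = Path(path)
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    st = _to_gemmi(model)
    if fmt == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    elif fmt == "pdb":
        st.write_pdb(str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# score sidecars
# ---------------------------------------------------------------------------

@dataclass
class ScoreEntry:
    combined: float
    iptm: float | None = None
    ptm: float | None = None
    relaxed: bool = True

    def __post_init__(self):
        for v in (self.combined, self.iptm, self.ptm):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"score {v} outside [0, 1]")
        if self.iptm is not None and self.ptm is not None:
            expect = IPTM_WEIGHT * self.iptm + PTM_WEIGHT * self.ptm
            if abs(self.combined - expect) > 1e-9:
                raise ValueError("combined score inconsistent with components")


@dataclass
class ScoreSidecar:
    entries: dict[str, ScoreEntry] = field(default_factory=dict)

    def __getitem__(self, model_name: str) -> ScoreEntry:
        if model_name not in self.entries:
            raise KeyError(f"no score recorded for model {model_name!r}")
        return self.entries[model_name]

    def __contains__(self, model_name: str) -> bool:
        return model_name in self.entries


def combine_scores(iptm: float, ptm: float) -> float:
    """Weighted model-confidence score 0.8*ipTM + 0.2*pTM."""
    return IPTM_WEIGHT * iptm + PTM_WEIGHT * ptm


def read_scores(path) -> ScoreSidecar:
    """Read a JSON score sidecar (component-wise or precombined dialect)."""
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh)
    sidecar = ScoreSidecar()
    if "iptm+ptm" in data:                      # AlphaFold ranking style
        relaxed_map = data.get("relaxed", {})
        for name, val in data["iptm+ptm"].items():
            sidecar.entries[name] = ScoreEntry(
                combined=float(val), relaxed=bool(relaxed_map.get(name, True)))
        return sidecar
    for name, rec in data.items():
        if not isinstance(rec, dict):
            raise ParseError(f"{path}: malformed score record for {name!r}")
        if "iptm" in rec and "ptm" in rec:
            iptm, ptm = float(rec["iptm"]), float(rec["ptm"])
            entry = ScoreEntry(combined=combine_scores(iptm, ptm),
                               iptm=iptm, ptm=ptm,
                               relaxed=bool(rec.get("relaxed", True)))
        elif "combined" in rec:
            entry = ScoreEntry(combined=float(rec["combined"]),
                               relaxed=bool(rec.get("relaxed", True)))
        else:
            raise ParseError(f"{path}: score record for {name!r} lacks "
                             "iptm/ptm or combined")
        sidecar.entries[name] = entry
    return sidecar


def write_scores(sidecar: ScoreSidecar, path) -> Path:
    data = {}
    for name, e in sidecar.entries.items():
        rec: dict = {"relaxed": e.relaxed}
        if e.iptm is not None and e.ptm is not None:
            rec.update(iptm=e.iptm, ptm=e.ptm)
        else:
            rec["combined"] = e.combined
        data[name] = rec
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)
    return path


# ---------------------------------------------------------------------------
# scored oligomers
# ---------------------------------------------------------------------------

@dataclass
class ScoredOligomer:
    """An oligomer model plus confidence scores and subchain provenance.

    `residue_offset` maps subchain numbering to full-length numbering
    (full = subchain + offset); 0 when the model already uses full-length
    author numbers.
    """

    model: StructureModel
    score: ScoreEntry
    subchain_id: str = "full"
    residue_offset: int = 0
    full_length: int | None = None

    def __post_init__(self):
        if self.n_copies < 2:
            raise ValueError("an oligomer needs at least 2 chains")
        seqs = {c.sequence for c in self.model.chains}
        if len(seqs) > 1 and self.subchain_id != "p1_heterodimer":
            raise ValueError("homo-oligomer chains must share one sequence")

    @property
    def n_copies(self) -> int:
        return len(self.model.chains)

    def full_res_ids(self, chain: Chain) -> np.ndarray:
        return np.asarray(chain.res_ids, dtype=int) + self.residue_offset

    @property
    def chain_length(self) -> int:
        """Residue count of the full protein chain (for per-100aa rates)."""
        if self.full_length is not None:
            return self.full_length
        return self.model.chains[0].n_res


# ---------------------------------------------------------------------------
# domain FASTA (one domain per sequence line)
# ---------------------------------------------------------------------------

def write_domain_fasta(header: str, domain_seqs: list[str], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{header}\n")
        for seq in domain_seqs:
            fh.write(seq + "\n")
    return path


def read_domain_fasta(path) -> tuple[str, list[str]]:
    """Read a FASTA whose line breaks delimit domains of one record."""
    path = Path(path)
    lines = [ln.rstrip() for ln in open(path) if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise ParseError(f"{path}: expected a FASTA header line")
    header = lines[0][1:].strip()
    domains = [ln for ln in lines[1:] if not ln.startswith(">")]
    if not domains:
        raise ParseError(f"{path}: no domain sequences found")
    return header, domains
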