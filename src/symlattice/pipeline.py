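"""End-to-end lattice assembly from a directory of scored oligomer models.

Stages run in order: domain identification on the monomer (when
present), axis detection on every oligomer, quality filtering,
interface clustering, axis-pair ranking, superposition, termination
checks, unit-cell extraction and mmCIF emission.  Every stage logs its
in/out counts; the run stops with an explicit reason code (recorded in
the report, exit without a lattice) when fewer than two axis clusters
survive or a termination condition fires -- by design no layer is
emitted for proteins with a single rotational axis.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import assembly, clustering, domains, filters, io, symmetry
from .config import PipelineConfig
from .sse import assign_sse


def _stage(log: list, name: str, n_in: int, n_out: int, **extra):
    rec = {"stage": name, "in": n_in, "out": n_out}
    rec.update(extra)
    log.append(rec)


def load_inputs(input_dir, config: PipelineConfig | None = None):
    """Oligomer models + sidecar scores (+ optional monomer) from a dir.

    Expects ``scores.json`` plus one mmCIF/PDB per model (stem = model
    name in the sidecar); ``monomer.cif`` feeds the domain stage.
    """
    input_dir = Path(input_dir)
    score_path = input_dir / "scores.json"
    if not score_path.exists():
        raise FileNotFoundError(f"missing score sidecar: {score_path}")
    sidecar = io.read_scores(score_path)
    monomer = None
    oligomers = []
    for path in sorted(input_dir.iterdir()):
        if path.suffix.lower() not in (".cif", ".mmcif", ".pdb"):
            continue
        if path.stem == "monomer":
            monomer = io.read_structure(path)
            continue
        if path.stem not in sidecar:
            continue
        model = io.read_structure(path)
        if len(model.chains) < 2:
            continue
        oligomers.append(io.ScoredOligomer(
            model=model, score=sidecar[path.stem],
            subchain_id="p1_heterodimer"
            if len({c.sequence for c in model.chains}) > 1 else "full"))
    return oligomers, monomer


def shared_domain_residues(olig_a: io.ScoredOligomer, olig_b: io.ScoredOligomer,
                           partition: domains.DomainPartition | None):
    """Full-length residues of the domains covered by both subchains.

    Falls back to the raw residue intersection when no partition is
    available; returns (shared_res, pivot_res).
    """
    res_a = set(olig_a.full_res_ids(olig_a.model.chains[0]).tolist())
    res_b = set(olig_b.full_res_ids(olig_b.model.chains[0]).tolist())
    common = res_a & res_b
    if partition is None or len(partition) == 0:
        return sorted(common), None
    shared, unshared = [], []
    for s, e in partition.intervals:
        dom = set(range(s, e + 1))
        if dom <= common:
            shared.append((s, e))
        else:
            unshared.append((s, e))
    if not shared:
        raise assembly.CannotConnectError(
            "no full domain shared between the two complexes")
    shared_res = [r for s, e in shared for r in range(s, e + 1)]
    pivot_res = None
    if unshared:
        # linker between the shared block and the nearest unshared domain
        se = max(e for _, e in shared)
        ss = min(s for s, _ in shared)
        after = [s for s, _ in unshared if s > se]
        before = [e for _, e in unshared if e < ss]
        if after:
            pivot_res = [r for r in range(se + 1, min(after)) if r in common]
        elif before:
            pivot_res = [r for r in range(max(before) + 1, ss) if r in common]
    return shared_res, pivot_res or None


def _symplot_rows(complexes, cluster_of):
    rows = ["subchain\tn_copies\torder\tscore\tcluster"]
    for sc in complexes:
        rows.append(f"{sc.oligomer.subchain_id}\t{sc.oligomer.n_copies}\t"
                    f"{sc.axis.order_k}\t{sc.score:.3f}\t"
                    f"{cluster_of.get(sc.name, '-')}")
    return "\n".join(rows) + "\n"


def run_pipeline(config: PipelineConfig, input_dir, out_dir) -> dict:
    """Run all stages; returns the report dict (also written as JSON)."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    report: dict = {"mode": config.mode, "config": config.to_dict(),
                    "stages": log, "stopped": None}

    oligomers, monomer = load_inputs(input_dir, config)
    _stage(log, "load", 0, len(oligomers))

    partition = None
    if monomer is not None:
        assign_sse(monomer)
        partition = domains.identify_domains(monomer, config)
        chain = monomer.chains[0]
        io.write_domain_fasta(
            monomer.name, domains.domain_sequences(chain, partition),
            out / "domains.fasta")
        (out / "domains.tsv").write_text(
            domains.domain_report(monomer, partition, config))
        report["domains"] = [list(iv) for iv in partition.intervals]
        _stage(log, "domains", 1, len(partition))

    if config.mode == "p1":
        return _run_p1(config, oligomers, monomer, partition, out, report, log)

    # detection + filtering
    complexes = []
    rejections = {}
    for olig in oligomers:
        assign_sse(olig.model)
        result = symmetry.detect(olig, mode=config.mode, config=config)
        if isinstance(result, symmetry.AxisRejection):
            rejections[olig.model.name] = result.reason
            continue
        outcome = filters.apply_filters(olig, config.mode, config)
        if not outcome.passed:
            rejections[olig.model.name] = ",".join(outcome.reasons)
            continue
        complexes.append(result)
    report["rejections"] = rejections
    _stage(log, "detect+filter", len(oligomers), len(complexes))
    if not complexes:
        report["stopped"] = "no_symmetry_complexes"
        _write_report(report, out)
        return report

    # clustering
    graph = clustering.build_graph(complexes, config)
    clusters = clustering.louvain_partition(graph, seed=config.seed)
    cluster_of = {sc.name: ci for ci, cl in enumerate(clusters)
                  for sc in cl.members}
    (out / "symplot.tsv").write_text(_symplot_rows(complexes, cluster_of))
    report["clusters"] = [
        {"members": [sc.name for sc in cl.members],
         "consensus_order": cl.consensus_order,
         "representative": cl.representative.name,
         "support": cl.support} for cl in clusters]
    report["louvain_seed"] = config.seed
    _stage(log, "cluster", len(complexes), len(clusters))
    if len(clusters) < 2:
        report["stopped"] = "one_axis_only"
        _write_report(report, out)
        return report

    pairs = clustering.rank_pairs(clusters)
    attempts = []
    for ci_a, ci_b, rep_a, rep_b in pairs:
        try:
            shared, pivot = shared_domain_residues(
                rep_a.oligomer, rep_b.oligomer, partition)
        except assembly.CannotConnectError as exc:
            attempts.append({"pair": [rep_a.name, rep_b.name],
                             "error": f"cannot_connect: {exc}"})
            continue
        extra = [cl.representative for cl in clusters
                 if cl not in (ci_a, ci_b)]
        if config.mode == "capsid":
            tile = assembly.assemble_capsid_tile(rep_a, rep_b, shared, config)
            scores = assembly.score_tile(tile, config)
            io.write_structure(tile.merged_model(), out / "tile.cif")
            report["tile"] = {
                "pair": [rep_a.name, rep_b.name],
                "axis_tilts_deg": [round(t, 3) for t in tile.tilt_angles()],
                "score_bend": scores.score_bend,
                "score_clash": scores.score_clash,
                "score_quality": scores.score_quality}
            _stage(log, "assemble", len(pairs), 1)
            _write_report(report, out)
            return report
        try:
            result = assembly.assemble_pair(rep_a, rep_b, shared,
                                            pivot_res=pivot, extra_B=extra,
                                            config=config)
        except (assembly.CannotConnectError,
                assembly.GapTooLargeError) as exc:
            attempts.append({"pair": [rep_a.name, rep_b.name],
                             "error": str(exc)})
            continue
        attempts.append({"pair": [rep_a.name, rep_b.name],
                         "termination": result.termination,
                         "score_quality": result.scores.score_quality})
        if result.ok:
            io.write_structure(result.tile.merged_model(), out / "tile.cif")
            assembly.emit_lattice(result.lattice, out / "lattice.cif")
            report["assembly"] = {
                "pair": [rep_a.name, rep_b.name],
                "group": result.cell.group,
                "cell": {"a": result.cell.a, "b": result.cell.b,
                         "gamma": result.cell.gamma},
                "score_clash": result.scores.score_clash,
                "score_bend": result.scores.score_bend,
                "score_quality": result.scores.score_quality,
                "n_B_copies": len(result.tile.B_copies),
                "n_peripheral_A": len(result.tile.peripheral_A)}
            _stage(log, "assemble", len(pairs), 1)
            _write_report(report, out)
            return report
    report["attempts"] = attempts
    report["stopped"] = "no_viable_pair"
    _stage(log, "assemble", len(pairs), 0)
    _write_report(report, out)
    return report


def _run_p1(config, oligomers, monomer, partition, out, report, log):
    if monomer is None:
        raise FileNotFoundError("p1 mode requires monomer.cif in the input")
    hets = []
    for olig in oligomers:
        if len(olig.model.chains) != 2:
            continue
        bound = olig.model.chains[1]
        interval = (bound.res_ids[0], bound.res_ids[-1])
        if partition is not None:
            # snap to the partition domain containing the bound chain
            for s, e in partition.intervals:
                if s <= interval[0] and interval[1] <= e:
                    interval = (s, e)
                    break
        hets.append((olig.model, olig.score, interval))
    _stage(log, "heterodimers", len(oligomers), len(hets))
    try:
        lattice = assembly.assemble_p1(monomer, hets, config)
    except (assembly.P1InsufficientError,
            assembly.DegenerateCellError) as exc:
        report["stopped"] = f"{type(exc).__name__}: {exc}"
        _write_report(report, out)
        return report
    assembly.emit_lattice(lattice, out / "lattice.cif")
    report["assembly"] = {
        "group": "p1",
        "cell": {"a": lattice.cell.a, "b": lattice.cell.b,
                 "gamma": lattice.cell.gamma}}
    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path):
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
    with open(out / "log.jsonl", "w") as fh:
        for rec in report["stages"]:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (frozenset, set, tuple)):
        return sorted(obj) if isinstance(obj, (frozenset, set)) else list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
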