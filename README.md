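# symlattice

Assembly of two-dimensional symmetric protein lattices — bacterial and
archaeal surface layers (S-layers) and, in curved mode, viral capsid
tiles — from scored oligomer coordinate models.

S-layers are crystalline protein arrays that coat many prokaryotic
cells.  Their self-assembly makes them hard to solve experimentally,
but modern complex-structure predictors produce good oligomer models of
the subunits.  `symlattice` turns a directory of such models (PDB/mmCIF
plus a JSON sidecar of ipTM/pTM confidence scores) into the minimal
description of the assembled layer: the wallpaper group (p1, p2, p3,
p4 or p6), the unit-cell constants (a, b, γ) and the symmetry operators
that regenerate the full lattice from one monomer.

## Method

1. **Domain segmentation.**  A monomer model is split into structural
   domains by local crosslinking of secondary-structure elements,
   iterative merging of subsections (by contacts, surface areas and
   lengths) and contact-minimising linker cropping; from the partition a
   set of five subchains (full length, no N-/C-terminal domain, first
   and last third of the domains) is derived for oligomer prediction.
2. **Axis detection.**  Each oligomer's chain-to-chain rigid transforms
   are decomposed into screw motions; a consensus rotational axis is
   fitted and its order k deduced from the inter-monomer angle Δφ ≈
   360°/k, k ∈ {2, 3, 4, 6} (plus 5 on curved shells).  Partial
   representations count: a trimer with 60° steps describes half of a
   6-fold axis.  Axes are accepted only if every monomer deviates ≤ 5 Å
   from its ideal rotational image.
3. **Filtering.**  Models pass a weighted confidence gate
   (0.8·ipTM + 0.2·pTM ≥ 0.2; homodimer pre-filter at 0.3), global and
   windowed steric-clash limits, and an intermolecular β-strand filter.
4. **Interface clustering.**  Surviving symmetry complexes are compared
   through interface distograms; Pearson correlations of the contact
   patterns weight a graph that the Louvain method partitions into
   candidate lattice axes.
5. **Superposition and scoring.**  The higher-order axis (A) is aligned
   to z; copies of the second complex (B) are superposed onto each A
   monomer via the shared domain, re-rotated parallel to z about the
   connecting linker, and A is propagated back onto the B monomers.
   The tile is scored by

       score_clash   = N_clashes / N_res
       score_bend    = (2/π) · sqrt(mean φ_i²)     (φ_i = B-axis tilts)
       score_quality = score_clash + score_bend

6. **Unit cell.**  Lattice vectors are symmetry-averaged translations
   between the central and propagated A complexes; the cell is snapped
   to its group constraints and emitted as mmCIF with explicit
   operators.  The run terminates (no lattice is invented) when axes
   tilt beyond 45°, the overlap gap is too large, the extracted cell
   contradicts the superposed model, or the folding unit is not rigid.

A synthetic-fixture generator (`symlattice.fixtures`) replaces the
structure predictor at desk scale: pseudo-protein monomers around k-fold
axes, planted wallpaper lattices with known cell constants, an
icosahedral vertex/face patch, and controllable score sidecars.

## Worked example

Generate a planted p4 lattice (a = 100 Å) and run the pipeline:

```
$ symlattice fixtures --group p4 --out fixdir --seed 7
$ symlattice run fixdir --out outdir
{
 "cell": {
  "a": 100.00000000000001,
  "b": 100.00000000000001,
  "gamma": 90.0
 },
 "group": "p4",
 "n_B_copies": 4,
 "n_peripheral_A": 8,
 "pair": ["p4_axisA_s7", "p4_axisB_s7"],
 "score_bend": 0.0,
 "score_clash": 0.0,
 "score_quality": 0.0
}
```

The two planted 4-fold axes were detected, clustered into two interface
groups, and superposed: four B copies surround the central A complex,
eight propagated A copies mark the neighbouring lattice points, and the
extracted cell (a = b = 100 Å, γ = 90°) matches the planted ground
truth with a perfect quality score (no clashes, no bending).
`outdir/` contains the unit-cell mmCIF (`lattice.cif`), the
pre-idealisation tile, the per-axis scatter table (`symplot.tsv`), the
domain FASTA and a full JSON report.  A single detected axis stops the
run with `one_axis_only` instead of emitting a layer.

For a p1 layer (no rotational axes), run with `--mode p1` on
full-length/single-domain heterodimers; for capsids, `--mode capsid`
admits 5-fold axes and reports the inter-axis tilt of the curved tile
(37.38° for an icosahedral vertex/face pair) instead of a cell.

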