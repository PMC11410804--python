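# Methods

## Scope and model

`symlattice` reconstructs a planar (or locally curved) protein lattice
from oligomer models of one protein.  The underlying model is that a
2D crystal is generated by two rotational symmetry axes: around each
axis the subunits are related by rotations of 360°/k, and the two axis
stars share at least one domain of the subunit, so that superposing the
shared domain chains propagates the lattice.  The five wallpaper groups
that single-protein S-layers occupy (p1, p2, p3, p4, p6) are supported;
curved (capsid) tiles relax the requirement that the two axes be
parallel and admit 5-fold axes.

## Pipeline stages and the parameters that matter

All thresholds live in `PipelineConfig` and are serialised into every
report.  Units are Å and degrees unless stated.

**Confidence gates.**  Oligomer models carry a weighted confidence
score 0.8·ipTM + 0.2·pTM ∈ [0, 1].  Homodimer pre-screening requires
≥ 0.30 (`min_score_prefilter`); the symmetry stage requires ≥ 0.20
(`min_score_symmetry`), inclusive at the boundary.

**Axis detection.**  Chain pairs are superposed by least-squares
(Kabsch) on CA atoms matched by residue number; each transform is
decomposed into rotation angle, axis, anchor and screw shift.  The
consensus direction is the principal eigenvector of the orientation
tensor over all pairwise axes; chains are ordered by azimuth around it.
The order k minimises |Δφ − 360/k| over the allowed orders subject to
m ≤ k, accepted within `angle_tol` = 10°.  Axis uniformity: rotating
each monomer's predecessor centroid by 360/k about the consensus axis
must land within `axis_dev_max` = 5 Å of the monomer centroid.  The
deviation is measured perpendicular to the axis; translation along the
axis is assessed separately as the screw shift (`screw_tol` = 3 Å per
step in layer mode, unrestricted on curved shells).  Axis directions
are normalised into the +z hemisphere.

**Clash gates.**  A clash is an inter-chain heavy-atom pair closer than
r_i + r_j − 0.6 Å (van der Waals radii C 1.70, N 1.55, O 1.52, S 1.80,
P 1.80; unknown elements 1.70).  Relaxed models fail at ≥ 3.0 clashes
per 100 aa of the protein chain, or above 6.0 per 100 aa inside any
200-aa sequence window; unrelaxed thresholds are 20× looser (60 / 120).
The global rule is exclusive at the threshold, the window rule
inclusive, following the asymmetry of the published wording ("at least
… are excluded" vs "only … are allowed").

**β-strand filter.**  Hydrogen bonds are detected with the classic
electrostatic criterion (amide H rebuilt from the previous peptide
plane, E < −0.5 kcal/mol); β bridges use the standard
parallel/antiparallel ladder conditions.  Models fail when more than
`beta_max` = 0.25 of their residues join inter-chain bridges — the
paper gives no number for "unusually high", so this is the package's
own operating point, chosen so that occasional spurious bridges pass
while interface-spanning sheets (≥ 40 % of residues in the
constructed ladders) fail.

**Interface clustering.**  The interface of a complex is the distogram
of minimum heavy-atom distances between the angularly first chain and
its successor, capped at `d_cap` = 10 Å and indexed in full-length
numbering so that differently cropped subchains remain comparable.
Edges of the complex graph carry Pearson correlations of the binarised
(< 5 Å) patterns over shared positions (≥ 20 required); edges below
`w_min` = 0.2 are dropped.  Louvain community detection (networkx)
runs with a seed derived from the configured seed and a hash of the
sorted node names, making the partition invariant to input order.
Cluster consensus order is a score-weighted vote with ties going to the
higher order, because several molecule counts pointing at one axis
(e.g. a 60°-step trimer plus a hexamer) are the strongest evidence.

**Assembly.**  Axis pairs are ranked by the minimum of the two cluster
representatives' scores; lower-scored members are fallbacks.  The
higher-order complex is the central A.  B copies are placed by Kabsch
superposition of the shared-domain CA onto each A monomer; a placement
whose overlap RMSD exceeds `gap_max` = 5 Å aborts the pair ("the
complexes cannot be connected").  The recorded tilt of each placed B
axis against the central axis feeds the bending score before the axis
is re-rotated parallel to z about the pivot (the centroid of the linker
residues between shared and unshared domains; the shared-region
centroid when the complexes share everything).  A copies are propagated
onto the B monomers the same way; placements whose axis lands on an
existing anchor (within 1 Å in xy) are duplicates and dropped.

**Scores.**  score_clash is the inter-chain clash count of the merged,
monomer-deduplicated tile divided by its residue count; all residues in
the scored tile enter the denominator.  score_bend is
(2/π)·sqrt(mean φ_i²) over all directly placed B copies (the "nearest
neighbour" set), mapping 0 rad → 0 and π/2 rad → 1.  score_quality is
their sum; lower is better, and the planted configuration outranks
tilted or deformed decoys.

**Unit cell.**  Translations from the central to the propagated A
complexes are grouped into ±direction classes (20° cone); the shortest
class mean is v1 and the second vector is the class whose angle best
matches the group's ideal γ (120° for p3/p6, 90° for p4; shortest
otherwise).  Lengths are averaged within each class, the cell snapped
exactly to the group constraints, and the group itself follows the
maximum detected axis order (6→p6, 4→p4, 3→p3, 2→p2).  The 2D cell is
embedded in a 3D crystallographic cell with c = 500 Å, α = β = 90°;
operators (from the corresponding space-group settings P 1, P 1 1 2,
P 3, P 4, P 6) leave z unchanged and are written explicitly to the
mmCIF, so re-reading and applying them regenerates the tile.

**Termination.**  A pair is abandoned, and the run stops if no pair
remains, when: any B-axis tilt exceeds `tilt_max` = 45°; any overlap
RMSD exceeds `gap_max`; a propagated translation deviates more than
`cell_dev_max` = 10 % from its class mean; or the median pairwise CA
RMSD between the central complex's monomers exceeds `rigid_max` =
2.5 Å (no rigid folding unit).  Runs with fewer than two axis clusters
stop with `one_axis_only`: a single rotational axis cannot span a
layer, and none is fabricated.

**p2 lattices.**  Two 2-fold axes generate only a 1D repeat (the
composite of two half-turns is a translation along their connecting
line), so a p2 layer cannot be spanned by one axis pair.  When the
propagated translations of the leading pair are collinear, the driver
draws the representative of the next interface cluster into the same
tile and re-extracts the cell — the analogue of testing further pairs
when no clear result is found.  The p2 fixture accordingly plants three
2-fold axis classes.

**p1 route.**  Without rotational axes, heterodimers of the full-length
protein with each single domain are examined; every strong interaction
(score ≥ 0.2, overlap RMSD ≤ `gap_max`) yields the translation that
maps the full-length model onto the bound domain.  Two non-collinear
translations (≥ 10° apart) define the oblique cell; fewer stop the run.

**Domain segmentation.**  Subsections seed from runs of H/E secondary
structure (isolated calls shorter than 3 residues are ignored as
noise); consecutive elements sharing ≥ `k_link` = 8 residue contacts at
5 Å join one subsection.  Adjacent subsections are merged greedily by
s(i,j) = contacts(i,j) / (√min(surface) · √min(length)) until the best
score falls below `tau_merge`; contacts within two sequence positions
are excluded everywhere in this stage, since covalent adjacency is not
interface evidence.  With that exclusion the calibrated saturation
threshold is `tau_merge` = 0.01: bodies in genuine contact (≈ 6+
non-local contact pairs for 44-residue test bodies) merge, bodies with
no contact never do, and tightly packed helix pairs score an order of
magnitude above the threshold.  Cropping then moves each boundary to
the coil residue minimising contacts across the cut, ties resolved
towards the linker midpoint.  Domains shorter than `min_domain_len` =
25 aa are absorbed into a neighbour.  Subchains are clamped to
[120, 1200] aa, extending or truncating away from their anchored end.

**Surface areas** are numeric solvent-accessible areas (deterministic
Fibonacci sampling, 240 points per atom, probe 1.4 Å) of the selection
treated as an isolated unit.

## What the generator emulates — and what it does not

`symlattice.fixtures` builds rigid pseudo-monomers (three-helix bundles
with ideal backbone dihedrals, CB but no further side chain, joined by
fabricated coil linkers), places them around k-fold axes or into exact
wallpaper lattices, adds isotropic Gaussian coordinate noise, and emits
mmCIF plus score sidecars with chosen ipTM/pTM.  Interface spacings are
tuned numerically so ring neighbours touch at 4.2 Å — inside the 5 Å
contact cutoff, outside clash range.  Default study conditions: 44–50
residues per domain, lattice constants 80–170 Å by group (p1 defaults
73/89 Å, γ = 105°, an oblique cell at the scale reported for real p1
S-layers), noise σ ≤ 0.5 Å in the recovery experiments, 20 seeds per
group.

The fixtures are geometric, not energetic: no side-chain packing, no
prediction-like correlated error modes (domain rearrangements,
low-confidence floppy termini, register shifts), no membrane anchors,
and linker backbones do not satisfy covalent geometry.  Passing tests
therefore demonstrate that the geometry engine recovers planted
symmetry under coordinate noise — they do not certify performance on
real predictor output, whose failure modes are structured rather than
isotropic.

## Numerical choices

* Kabsch superposition enforces a proper rotation via the SVD sign
  correction; collinear point sets are rejected.
* Azimuthal chain ordering adds 1e-8 rad before wrapping to [0, 2π) so
  the reference chain cannot alias to 2π.
* Both senses of rotation are tried when checking axis uniformity; the
  better one is kept (the chain order around the axis is not assumed).
* Tie-breaks: k-selection prefers the smaller order at equal angular
  error; cluster consensus prefers the higher order at equal vote;
  merge candidates prefer the lower start index; crop cuts prefer the
  linker midpoint.
* The tilt termination uses a 1e-6 degree epsilon so a tile at exactly
  45° is not rejected by floating-point noise.
* Coordinates are written with 3 decimals; cell round-trips are exact
  to that precision.

## Known limitations

* No automated closure of a full icosahedral capsid: capsid mode stops
  at the curved tile and reports inter-axis angles.
* Single-protein lattices only; multi-protein S-layers are out of
  scope.
* The β-strand filter counts bridge residues; it does not model strand
  register or sheet topology.
* Secondary-structure assignment covers H/E/C only (the three states
  consumed downstream); 3-10 and π helices read as coil.
* The domain-merge functional is a calibrated stand-in for an
  unpublished criterion; its absolute scale is only meaningful relative
  to `tau_merge`.
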