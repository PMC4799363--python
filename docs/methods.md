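# Methods

## The rigid fusion-helix model

The toolkit treats an α-helix as a rigid parametric object: residue *i*'s Cα
sits on a cylinder of radius *r* ≈ 2.3 Å at height *i·d* and azimuth *i·ω*,
with rise *d* ≈ 1.5 Å/residue and twist *ω* ≈ 100°/residue. A chimera is
built by superposing the C-terminal helix of a donor domain and the
N-terminal helix of an acceptor domain onto consecutive registers of one
ideal helix template and carrying each whole domain along rigidly. The model
makes three assumptions, all inherited from the underlying design strategy:

1. the parent helices are close enough to ideal that a backbone
   superposition onto the template is meaningful (enforced: the build fails
   if either superposition RMSD exceeds 1.0 Å);
2. the fusion does not perturb the parents away from the seam (hence pure
   rigid motion — no energy refinement, repacking or structure prediction
   anywhere in the package);
3. orientation control follows from helix periodicity: inserting *k*
   residues between the junctions rotates the acceptor by *k·ω* about the
   helix axis and advances it *k·d* along it.

## Ideal-helix construction

Two builder modes:

- **dihedral** (default): backbone atoms are chained by internal coordinates
  (NeRF) with φ = −57°, ψ = −47°, ω = 180° and Engh–Huber-type bond
  lengths/angles (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; N–CA–C 111.2°,
  CA–C–N 116.2°, C–N–CA 121.7°). Cβ is placed by the standard idealized
  L-configuration construction from N/CA/C. These defaults *measure* as
  1.558 Å rise and 99.36°/residue twist through the axis fitter — the
  derived values are never asserted a priori, and the ~100°/residue
  observable is the binding one for orientation control.
- **helicoidal**: Cα are placed exactly on a helix of stated rise/twist/
  radius; the remaining backbone is carried over from a dihedral-mode
  template in cylindrical coordinates about its fitted axis (per-atom
  offsets from the Cα preserved). This mode exists to make the
  builder→fitter loop exactly invertible, which anchors the axis fitter's
  correctness at machine precision.

## Helix-axis fitting

`fit_helix_axis` is a least-squares cylinder fit. Initialization: second
differences of the Cα trace point radially inward, so cross-products of
successive second differences align with the axis; their sign-consistent
mean seeds the direction, the trace centroid seeds a point on the axis.
Refinement: nonlinear least squares (`scipy.optimize.least_squares`,
tolerances 1e-14) on the radial deviations r_i − r̄. The axis direction is
reported N→C so signed rotations are comparable across designs; rise is the
mean axial step, twist the mean signed rotation of radial unit vectors about
the axis, fit RMSD the radial deviation from the fitted cylinder. Traces
with near-zero radius (collinear points) or Cα spacing outside 2–5 Å are
rejected as degenerate. On exact helicoidal input the fit recovers the
generating parameters to < 1e-6; on ideal dihedral-mode helices it is
rigid-transform invariant to < 1e-9. On *bent* helices the cylinder model is
only approximate and the optimum is shallow; bend measurements therefore fit
the two halves separately (each half being nearly ideal) and report the
inter-axis angle.

Helix detection uses a permissive dihedral window (φ ∈ [−100°, −30°],
ψ ∈ [−80°, −5°], minimum run 5) rather than hydrogen-bond-based secondary
structure: the inputs of interest are helices by construction or by
crystallographic assignment, and a torsion rule works on backbone-only
models. Terminal residues with one undefined angle extend a run if the
defined angle is helical, so first/last turns are not clipped.

## Fusion construction and orientation measurement

`plan_terminal_fusion` records the register map (donor residues ≤ donor
junction → fused 1..n_d, then the insert, then acceptor residues ≥ acceptor
junction), requiring both junctions to lie inside their helices.
`build_fusion_model` builds the template for the full fusion-helix span,
superposes each parent's N/CA/C backbone span onto its register, transforms
each parent rigidly and merges. Acceptor residues are additionally
reportable with a +1000 author-style offset, mirroring the convention of
numbering a second fused component beyond 1000 to avoid collisions.

`relative_orientation` superposes the two designs' shared donor domains,
then finds the rigid transform between the two placements of the acceptor
(Kabsch on matched atoms). The rotation is decomposed as a signed angle
about the fusion-helix axis and reported in [0, 360); the axial translation
is the displacement of the acceptor-junction Cα along the axis. The total
acceptor-centroid displacement is reported alongside, because for a domain
whose centroid sits off-axis a 200° rotation moves the centroid much farther
than the ~3 Å axial advance — when comparing to descriptions of large
inter-variant movements, the centroid number is usually the relevant one,
and the toolkit deliberately reports both rather than guessing.

Clash detection lists inter-group heavy-atom pairs below a soft cutoff
(per-pair vdW-radius sum − 0.4 Å by default, Bondi-type radii) and counts
hard contacts below 2.5 Å, using a k-d tree whose counts are tested to equal
the brute-force all-pairs result. Insertion scans report, per insertion
count, the clash summary between the two domain bodies (fusion-helix span
excluded, since consecutive fused residues are covalently bonded) and the
rotation relative to the smallest variant.

Loop insertion builds the rigid connection only on the helix side (adaptor
C-terminal helix → target helix following the loop); the N-side flexible
linker (default GGGGS) appears in the designed sequence with no atoms and a
declared disordered segment, matching how such linkers appear (or fail to
appear) in crystal structures.

## Staple-site placement

The EY-CBS descriptor carries the chemistry the geometry needs: anchor
spacing 11 residues, target Cα–Cα distance 16.8 Å with acceptance window
15.5–18.1 Å (bracketing both crystallographic values and the 17.14 Å the
default ideal model produces), masked offsets {4, 7} → Ala, and the formula
C18H14Cl2N2O8S2 whose standard-atomic-weight sum rounds to 521 Da.
Candidate sites must straddle the junction (one cysteine per parent domain),
pass the distance window, and pass a solvent-exposure filter.

Exposure is proxied by a neighbor count: heavy atoms within 10 Å of the
position's Cβ, *excluding* same-chain residues within 4 in sequence. The
exclusion matters: one helical turn of the residue's own helix always fills
the neighborhood, so counting it would say nothing about whether the helix
face is packed against the rest of the structure. With the exclusion, an
isolated ideal-helix residue counts ~14 and a deliberately buried one ~74;
the default threshold is 22. This is a deterministic stand-in for a
judgement that is fundamentally visual/SASA-like; the threshold is a
documented default, not a derived constant.

Mutation application trims side chains past Cβ, renames residues, and models
cysteine SG at χ1 = −60°; Gly targets get a pseudo-Cβ constructed from the
backbone (noted in the model metadata). Alanine masking at i+4/i+7 is
recorded only when the position is not already Ala/Gly, and validation of
tabulated designs treats the masking as a soft criterion — among the 21
packaged records, several carry non-Ala residues at i+7 and are still valid
staple designs.

## Synthetic fixtures and what passing tests show

The generators produce ideal helices, kinked helices (second half rigidly
rotated about a perpendicular hinge at the kink residue — the kink angle is
exactly the inter-axis angle by construction), two-helix toy domains (two
ideal helices at a packing angle, joined by a short geometric loop), dense
blocking balls for burial tests, and seeded Gaussian coordinate noise. Every
fixture is deterministic given its spec and seed, and every fixture is
validated by the package's own estimators (kink recovery, helix counts,
clash-freeness), closing the generator↔estimator loop.

What the fixtures do *not* emulate: real side-chain packing, sequence-
dependent helix propensity, crystallographic disorder, and the experimental
question of whether a designed seam actually folds into a continuous helix
— in the underlying study only 5 of 21 designs reacted with the staple, an
outcome that geometry alone cannot predict and that this toolkit explicitly
does not attempt to predict. Passing tests demonstrate that the geometric
machinery is self-consistent and reproduces the geometric observables of
solved structures' *kind* (distances, twists, bends, groupings), not that
any particular new design will succeed.

## Numerical choices and problem sizes

- Superposition: Kabsch via SVD with determinant correction; reflections
  are never returned; collinear inputs are flagged but solved.
- Axis-fit tolerances 1e-14; staple χ1 fixed at −60°; clash soft slack
  0.4 Å; copy grouping by single linkage cut at 1.0 Å (or a requested k).
- NCS copy discovery: chains with ≥ 90% sequence identity over the shared
  numbering, pairwise Kabsch over shared Cα.
- Test and acceptance runs use desk-scale inputs — 20-residue helices,
  ~27-residue toy domains (~280 atoms per fused model), 10⁴-rotation
  optimality sampling — chosen so the whole suite completes in seconds
  while every property is exercised at full precision.

## Known limitations

- The PDB writer refuses residue numbers > 9999 (fixed-width columns);
  mmCIF is the lossless dialect.
- Only the first model of multi-model files is read; no assembly/symmetry
  expansion.
- The helicoidal builder's non-Cα atoms are approximate by design.
- No SG–SG or all-atom cross-linker placement: the staple is represented by
  its anchor-distance window, which is the quantity the design controls.
- Junction numbering in external design tables may follow database (UniProt/
  GenBank) numbering; mapping onto a particular coordinate file's author
  numbering is the caller's responsibility.
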