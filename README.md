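# helixfuse

Rigid fusion of two protein domains through a shared α-helix, stapled by a
bifunctional chemical cross-linker.

## The problem

Most chemical cross-linkers join proteins through long flexible spacers, so
the relative orientation of the linked domains is unpredictable. An
alternative is to merge two pre-existing helices — the C-terminal helix of one
domain and the N-terminal helix of another — into one continuous "fusion
α-helix". Because an ideal α-helix is a rigid unit that advances ~1.5 Å and
rotates ~100° per residue (3.6 residues/turn), a fused helix fixes the
inter-domain geometry, and inserting *k* residues at the junction rotates one
domain by ~*k*·100° about the helix axis. The fused helix is locked in place
by EY-CBS, a rigid cross-linker that bridges two cysteines engineered at
helix positions *i* and *i*+11 (three turns apart, same helix face, Cα–Cα
≈ 16.8 Å), with positions *i*+4 and *i*+7 mutated to alanine to clear the
linker's footprint. Reactivity with the staple doubles as a conformational
probe: only a genuinely continuous helix presents both cysteines correctly.

`helixfuse` is a toolkit for designing and checking such fusions:

- **structure_io** — PDB/mmCIF/FASTA I/O with author numbering preserved
  (gemmi-backed).
- **helix_geometry** — ideal α-helix builders (internal-coordinate and exact
  helicoidal modes), dihedral-based helix detection, least-squares helix-axis
  fitting (rise/twist/radius), bend angles, Kabsch superposition.
- **fusion_design** — rigid chimera construction on an ideal helix template,
  insertion scanning, clash detection, relative-orientation measurement, and
  loop-insertion designs with a flexible (unmodelled) GGGGS linker on the
  non-rigid side.
- **staple_design** — the EY-CBS cross-linker spec (C18H14Cl2N2O8S2, 521 Da),
  i/i+11 staple-site search across the junction with distance and
  solvent-exposure filters, cysteine/alanine mutation application, and
  validation of tabulated design records (21 published records ship with the
  package).
- **analysis_report** — fusion-helix measurements (staple Cα–Cα distance,
  bend, rise/twist), named pairwise contacts, NCS-copy RMSD grouping, and
  JSON/TSV/markdown reports.
- **fixtures** — deterministic synthetic structures (ideal/kinked helices,
  toy two-helix domains) used to validate every estimator against known
  ground truth.

## Worked example

Design a fusion between two toy helical domains, scan insertions, and staple
it:

```python
from helixfuse import (assign_helices, plan_terminal_fusion, build_fusion_model,
                       relative_orientation, find_staple_sites,
                       apply_staple_mutations)
from helixfuse.fixtures import make_two_helix_domain
from helixfuse.helix_geometry import segment_from_residues

donor = make_two_helix_domain();    donor.id = "donor"
acceptor = make_two_helix_domain(); acceptor.id = "acceptor"
dh = assign_helices(donor.chains[0])[-1]    # C-terminal donor helix
ah = assign_helices(acceptor.chains[0])[0]  # N-terminal acceptor helix

d0 = plan_terminal_fusion(donor, dh, dh.end, acceptor, ah, ah.start, n_insert=0)
build_fusion_model(d0)
d2 = plan_terminal_fusion(donor, dh, dh.end, acceptor, ah, ah.start, n_insert=2)
build_fusion_model(d2)
print(relative_orientation(d0, d2))

lo, hi = d0.fusion_span
chain = d0.fused_model.chains[0]
seg = segment_from_residues([r for r in chain.residues if lo <= r.seq_number <= hi])
for s in find_staple_sites(d0.fused_model, seg, d0.junction_fused):
    print(s.i_position, s.j_position, round(s.ca_distance, 2))
```

prints

```
OrientationDelta(rotation_deg=198.71064482141867, axis_translation=3.1155463549690494, centroid_displacement=11.797267051992606)
19 30 17.14
23 34 17.14
27 38 17.14
```

Two inserted residues rotate the acceptor domain by ~199° about the
fusion-helix axis (2 × the fitted 99.4°/residue twist) and advance it ~3.1 Å
along it; the candidate i/i+11 staple sites straddle the junction (fused
residue 27) with Cα–Cα ≈ 17.1 Å, inside the cross-linker's 15.5–18.1 Å
window. `apply_staple_mutations(d0, site)` then writes the Cys/Ala mutations
into the sequence and model.

The same workflow is available from the shell:

```sh
helixfuse design --donor donor.pdb --acceptor acceptor.pdb \
    --donor-junction 27 --acceptor-junction 1 --scan 0:6 \
    --out-model fused.pdb --out-seq fused.fa
helixfuse staple --model fused.pdb --helix-span A:17:38 --junction 27
helixfuse validate --table src/helixfuse/data/table1.tsv
helixfuse measure --structure fused.pdb --helix-span A:17:38 --cys 19:30
```

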