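# foldkit

Structure analysis and refolding-protocol tools for protein conformers:
sliding-window CA packing metrics, DSSP-style secondary structure,
structure-quality scores, cavity volumes, superposition RMSD tables, and
an adaptive staged-cooling refolding controller exercised against a
bundled coarse-grained folding simulator.

## Who this is for

Simulators and structural bioinformaticians who unfold and refold
proteins *in silico* and need desk-scale, reproducible machinery to (a)
quantify how packing and secondary structure change along a trajectory,
(b) run quality checks on the resulting conformers, and (c) drive — and
study — a cooling schedule that steps the temperature down a ladder when
the packing metrics signal instability.

## The core quantities

For a CA trace of N residues the packing profile comprises the i→i+2
distances |CA_i − CA_{i+2}| and, in the default centroid-anchored
variant, triangle areas A_i = area(CA_i, CA_{i+2}, CoG) and tetrahedron
volumes V_i = vol(CA_i, CA_{i+2}, CA_{i+4}, CoG), where CoG is the
unweighted CA centroid. Compact folds subtend small windows; swelling
shows up as a rise in the per-window means — the signal the refolding
controller watches. A chain-anchored variant (windows i, i+2, i+3,
i+4) probes local geometry instead.

Around these sit: Kabsch least-squares superposition restricted to
proper rotations with CA RMSD; Kabsch–Sander hydrogen-bond energies
(E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bond iff
E < −0.5) reduced to five secondary-structure classes (H, G, E, T, C);
backbone/packing/Ramachandran/chirality quality scores; and grid
flood-fill cavity volumes. The refolding engine is a Gō-style
structure-based CA model (native-contact wells, native torsions, weak
non-native attraction) driven by Metropolis Monte Carlo at reduced
temperature; folding progress is the native-contact fraction Q.
`docs/methods.md` documents every model and constant.

## Worked example

```python
from foldkit import (extract_ca_trace, darvols_profile,
                     assign_secondary_structure, quality_report)
from foldkit.refolding import build_go_model, unfold_stage, run_refolding_protocol
from foldkit.synthetic_fixtures import ideal_helix

helix = ideal_helix(30)                       # poly-Ala at (phi, psi) = (-57, -47)
trace = extract_ca_trace(helix)

prof = darvols_profile(trace, "cog")
ss = assign_secondary_structure(helix)
q = quality_report(helix)
print(f"mean area {prof.mean_area:.2f} A^2, %H {ss.pct_helix:.2f}, "
      f"bbc {q.bbc_z:.2f}, chirality violations {q.chirality_violations}")

model = build_go_model(trace)                 # 53 native contacts
unfolded = unfold_stage(model, seed=1)        # denature at reduced T = 5
refold = run_refolding_protocol(model, unfolded.final_positions(), seed=7)
print(f"Q: native 1.00 -> unfolded {unfolded.final_q():.2f} "
      f"-> refolded {refold.final_q():.2f}")
```

prints

```
mean area 24.54 A^2, %H 93.33, bbc -0.00, chirality violations 0
Q: native 1.00 -> unfolded 0.17 -> refolded 0.91
```

The helix is assigned ~93% helical, its backbone sits exactly at
reference geometry (score 0), and all residues are L-configured. The
protocol run denatures the chain until fewer than a fifth of its native
contacts survive, then recovers over nine-tenths of them by cooling
through the 300/200/100-labelled ladder, stepping down on packing
instability or stage expiry.

The same operations are available as a CLI:

```
foldkit darvols structure.pdb --variant cog --out metrics.tsv
foldkit report traj.pdb --reference crystal.pdb --out summary.tsv
foldkit refold-sim --config examples/refold_demo.yaml --seed 7 --out-prefix run
```

`report` emits one row per conformer with the fixed column order: total
cavity volume, mean area/volume, the five secondary-structure
percentages, the four quality scores and RMSD versus the reference.
`refold-sim` writes a CA-bead multi-model PDB trajectory, a metric TSV
(snapshot, temperature label, Q, mean area/volume) and an event log of
step-downs.

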