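# Methods

This note documents the models, conventions and numerical choices behind
foldkit, in the order the pipeline runs: structure I/O, packing metrics,
conformation analysis and quality scores, cavity detection, and the
staged-cooling refolding protocol with its bundled coarse-grained
simulator.

## Structure model and PDB conventions

All analyses consume a `StructureModel`: an ordered atom list with names,
elements, author residue numbers, chain identifiers and coordinates in Å.
Parsing and serialisation are delegated to gemmi; a pre-validation pass
over the raw text produces line-numbered errors for malformed coordinate
fields and rejects inputs with no ATOM records. Policies, chosen once:

* altLoc — keep blank or `A` alternate locations, drop the rest
  (single-conformer convention);
* HETATM and waters — excluded everywhere; the analyses concern the
  polypeptide chain only;
* insertion codes — distinct residues in file order, no renumbering;
* default chain — the first chain in file order;
* round-trip guarantee — read→write→read preserves residue counts, atom
  order, and coordinates to the format's fixed 3-decimal precision.

## Sliding-window packing metrics

For a CA trace of N residues the packing profile comprises i→i+2
distances (N−2 values) and triangle areas / tetrahedron volumes in two
variants:

* **cog** (default): areas over (CA_i, CA_{i+2}, CoG), N−2 values, and
  volumes over (CA_i, CA_{i+2}, CA_{i+4}, CoG), N−4 values, where CoG is
  the unweighted CA centroid. The trace representation carries no
  masses, so the "centre of gravity" is the coordinate mean.
* **chain**: areas over (CA_i, CA_{i+2}, CA_{i+3}) and volumes over
  (CA_i, CA_{i+2}, CA_{i+3}, CA_{i+4}), anchored on the chain itself.

The two definitions are not interchangeable — centroid-anchored windows
respond to global swelling, chain-anchored ones to local geometry — so
the variant is an explicit parameter. Both per-window means and sums are
reported, since the appropriate normalisation depends on whether chains
of different lengths are compared.

A caution discovered while validating: neither variant orders an *ideal
straight chain* above a helix. A chain that passes through its own
centroid subtends nearly degenerate triangles, so a perfectly extended
conformation scores *smaller* areas than a compact helix. The metrics
are packing-sensitive in the physically relevant regime — swelling or
expanding a globular conformation increases them, which is what the
refolding controller exploits — but they are not a general
"extendedness" measure. Tests assert the true form (inflation increases
centroid-anchored areas; thermally denatured states out-measure refolded
ones).

Superposition uses the Kabsch least-squares rotation restricted to
proper rotations (reflection branch rejected), via
`scipy.spatial.transform.Rotation.align_vectors`; RMSD is CA-only, the
common denominator across crystal, trajectory and ensemble inputs. The
test suite cross-checks it against an independent seeded quaternion grid
search.

## Backbone geometry and hydrogen bonds

Torsions follow the IUPAC convention, signed in (−180°, 180°]:
φ_i = (C_{i−1}, N_i, CA_i, C_i), ψ_i = (N_i, CA_i, C_i, N_{i+1}).
Terminal/undefined angles are NaN-flagged, never fabricated. Amide
hydrogens (absent from crystal structures and CA models) are placed
1.00 Å from N opposite the preceding carbonyl C→O direction; prolines
and chain starts get none.

Hydrogen bonds use the Kabsch–Sander electrostatic model,

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)  kcal/mol,

with a bond recorded iff E < −0.5 kcal/mol and |donor − acceptor| ≥ 2.
These constants are the de-facto standard behind five-class
secondary-structure statistics and are adopted verbatim.

## Secondary structure (five classes)

An n-turn exists at i when CO_i accepts the NH of residue i+n (n = 3, 4).
Assignment rules:

* **H** (α-helix): two consecutive 4-turns mark the four enclosed
  residues;
* **G** (3₁₀): two consecutive 3-turns, where not already helical;
* **E** (strand): residues in parallel/antiparallel bridges defined by
  the standard Kabsch–Sander bridge hydrogen-bond patterns;
* **T** (turn): residues enclosed by an isolated n-turn;
* **C** (coil): everything else. π-helix and bend are folded into
  turn/coil so that exactly five classes are reported.

Class priority is H > E > G > T > C. Percentages are 100·count/N (exact
floats internally; 2 decimals in reports), so the five always sum
to 100.

## Quality scores

These are openly specified analogues of the classic crystallographic
checking suite: sign conventions and orderings match (a good structure
scores near zero, degraded structures drift in the documented
direction), but the magnitudes are defined here and are *not* comparable
bit-for-bit with any proprietary program's output.

* **Backbone normality** — bond lengths (N–CA 1.458, CA–C 1.525,
  peptide C–N 1.329, C=O 1.231 Å) and the standard angle set,
  standardized by reference σ (0.014–0.02 Å, 1.7–2.8°); the score is the
  negated RMS standardized deviation. The synthetic backbone builder
  uses the same constants, so fixtures built at reference geometry score
  0 by construction.
* **Packing** — mean CA-neighbour count within 10 Å excluding sequence
  neighbours i±1, i±2, standardized against a compact-fold reference
  (mean 10.4, σ 2.0) calibrated once on the bundled compact helix-bundle
  fixture. Compact folds score near 0; fully extended chains fall below
  −2.
* **Ramachandran z-score** — mean log-density of the defined (φ, ψ)
  pairs under a packaged reference mixture: three bivariate Gaussian
  basins at (−63, −43), (−120, 130), (60, 45) with weights
  0.45/0.45/0.10 and σ = 15° per axis, periodic via nearest image.
  Calibration constants (mean and per-residue σ of the log-density) are
  computed once from a 200 000-point seeded sample of the mixture
  itself, so a structure drawn from the reference scores ≈ 0 and
  uniform torsions score far negative.
* **Chirality** — the CA improper ζ = dihedral(N, C, CA, CB), ≈ +34° for
  L-amino acids; negative ζ flags a D-configured residue. Glycines are
  exempt. Reported as a count plus the violation percentage.

## Cavity volumes

Grid flood fill: voxelise the bounding box (+2 Å margin) at 0.7 Å;
voxels within (vdW radius + probe) of any heavy atom are occupied (Bondi
radii C 1.70, N 1.55, O 1.52, S 1.80 Å; probe 1.4 Å; hydrogens ignored).
Empty voxels 6-connected to the boundary are bulk solvent; remaining
empty clusters are cavities, with volume = voxel count × grid³. On the
bundled hollow-shell fixture with a 5 Å accessible void the method
measures the analytic sphere volume within a few percent, and halving
the grid moves the estimate by well under 10%. Note the fixture
convention: the shell's `inner_r` is the *accessible* void radius — its
innermost atom-centre shell sits at inner_r + r_C + probe = inner_r +
3.1 Å — so analytic expectations hold at the default probe and radii.

## The coarse-grained refolding engine

The protocol controller is engine-agnostic; the bundled engine is a
structure-based (Gō-style) model at one bead per residue:

* harmonic virtual bonds, k_b = 10 ε/Å², rest length = mean native
  CA–CA distance;
* native contacts (|i−j| ≥ 3, native distance < 8 Å) interact through a
  12-6 well of depth ε = 1 with its minimum at the native distance;
* all other |i−j| ≥ 3 pairs carry excluded volume with a weak
  attraction: a 12-6 well of depth ε_nn = 0.25 at σ_ev = 4 Å;
* a native virtual-torsion term, k_dih(1 − cos(θ − θ_nat)) with
  k_dih = 2 ε, over every four consecutive beads.

Two of these terms deserve comment. First, pairwise distances are
invariant under mirror reflection, so a distance-only CA model cannot
tell the native fold from its enantiomer; refolds then anneal into
mixed-handedness segments whose boundaries cost contacts, and the
native-contact fraction Q plateaus near 0.5–0.7. The torsion term is
the minimal chirality-resolving addition (standard in CA
structure-based models) and restores a funnel to the true native state.
Second, a *purely* native-centric model is minimally frustrated: a
Metropolis chain always accepts downhill moves, so even a deep quench
folds it by greedy descent and no cooling schedule can matter. The weak
non-native attraction supplies the molten-globule stickiness of real
chains: collapsed states carry wrong contacts ~ε_nn deep that a
freezing-cold quench cannot escape (escape probability e^(−ε_nn/T)) but
a warm annealing stage clears easily. This is what gives the staged
protocol something real to be better at.

Dynamics are Metropolis Monte Carlo with single-bead Gaussian moves
(σ = 0.3 Å), fully deterministic given a seed. Temperatures are reduced
(units of ε). The running energy is updated incrementally per move and
agrees with a from-scratch recomputation to better than 1e-6 after 10⁴
moves. Equilibrium scans of the 30-residue helix model locate its
folding transition near reduced T ≈ 0.6–0.9, which anchors the
temperature ladder below.

Q counts a native contact as formed when its distance is within 1.2× the
native value.

## The staged-cooling protocol

Denaturation runs at reduced T = 5.0 (the ladder-topping "5000-degree"
stage) until Q < 0.2 or the snapshot budget is exhausted (flagged, exit
code 4 from the CLI). Recovery then starts at the hottest cooling stage
and steps down one stage whenever the instability rule triggers or the
stage's snapshot budget expires:

* instability rule: relative rise of the mean window area above its
  minimum over the trailing 5 snapshots exceeding 30% (window,
  threshold and metric are configurable) — rising packing metrics
  signal that the current temperature has become counter-productive.
  The default threshold sits above the measured noise floor of the
  metric on this engine (90th-percentile spontaneous rises ≈ 10%,
  extremes ≈ 20% at every temperature), so it fires on genuine
  sustained deterioration rather than equilibrium fluctuation; with a
  lower threshold the controller pops out of productive stages within a
  few snapshots on pure noise. The mean-volume series is several times
  noisier than the area series, hence area is the default trigger;
* default ladder: nominal labels 300/200/100 °C mapped to reduced
  temperatures 1.2 / 0.35 / 0.02 with stage budgets 24 / 74 / 2
  snapshots of 1200 moves — duration proportions of 1.2 : 3.7 : 0.1 at
  toy scale. The hot stage samples broadly above
  the folding transition, the middle stage does the annealing just
  below it, and the short freezing stage locks the result in;
* termination: ladder exhaustion, or a plateau of the area metric
  (relative spread < 0.5% over the rule window) on the final stage. The
  plateau tolerance is deliberately strict: measured area fluctuations
  at annealing temperatures are 2–5% both while still folding and when
  folded, so a looser tolerance stops runs mid-fold.

On the 30-residue helix model the full cycle denatures to Q ≈ 0.15–0.2
and recovers to Q ≈ 0.83–0.92 across seeds, while an equal-budget
single-stage quench at the freezing temperature locks in non-native
contacts and ends near Q ≈ 0.75–0.85. The staged ladder's median final
Q exceeding the quench's demonstrates, at desk scale, the protocol's
rationale: a critical elevated temperature is needed for the chain to
descend into its correct fold before the result is frozen in.

## What the synthetic fixtures do and do not show

All test inputs are generated programmatically: dihedral-defined
poly-alanine backbones (sequential torsion/angle/length placement;
measuring φ/ψ on a built backbone recovers the spec to ≪ 0.5°), ideal
helix (−57, −47) and strand (−139, 135) chains, an antiparallel strand
pair placed into hydrogen-bond register by minimising the Kabsch–Sander
energies of the intended inter-strand pairs under a rigid (proper)
transform, hollow shells for cavity analytics, mirror images, Gaussian
conformer ensembles, and compact helix bundles for packing calibration.

These fixtures have known answers by construction, which is what makes
the oracle tests possible; they are *not* realistic proteins. They carry
no side chains beyond CB, no sequence variety, no solvent, and the
30-residue engine fixture has a deliberately funnelled landscape.
Passing tests therefore demonstrate that the metrics, assigners, scores
and the protocol controller behave as specified on inputs with known
ground truth — not that the toy engine reproduces the thermodynamics of
a real 34 kDa enzyme. Trajectory-scale numbers for real proteins
require all-atom simulations and are out of scope here.

## Numerical details and degenerate inputs

* Degenerate geometry returns 0 (collinear triangles, coplanar
  tetrahedra) rather than raising; torsions on coincident points raise.
* Sliding-window profiles require N ≥ 5; superposition requires ≥ 3
  points and equal lengths; packing requires ≥ 20 residues; the
  Ramachandran score requires ≥ 10 defined (φ, ψ) pairs.
* Structures too sparse for hydrogen-bond detection degrade to coil
  with a warning instead of failing.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give bitwise-identical
  trajectories and byte-identical CLI outputs.

## Problem sizes

Default analysis and test sizes: 8–30-residue fixture chains, a
~3500-atom cavity shell on a ~50³–100³ voxel grid, and protocol runs of
~10⁵ Monte-Carlo moves (one denaturation plus five staged recoveries and
five matched quenches). These sizes give stable, reproducible statistics
for every assertion while keeping a full run of the suite on a single
CPU in the minutes range.
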