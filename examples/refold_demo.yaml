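# Demo configuration for `foldkit refold-sim`.
#
# The native reference is a 30-residue ideal helix built by the fixture
# module; the ladder maps the nominal 300/200/100 degree stage labels to
# reduced simulator temperatures with durations in the published
# 1.2 : 3.7 : 0.1 proportion.

model:
  native: helix          # helix | strand | path to a PDB file
  n_residues: 30
  contact_cutoff: 8.0    # Å, native-contact definition

unfold:
  temperature: 5.0       # reduced T of the denaturation stage
  max_snapshots: 60
  q_unfold: 0.2          # stop when Q drops below this

ladder:
  snapshot_interval: 1200   # Monte-Carlo moves between snapshots
  stages:
    - {label: 300, reduced_t: 1.2,  max_snapshots: 24}
    - {label: 200, reduced_t: 0.35, max_snapshots: 74}
    - {label: 100, reduced_t: 0.02, max_snapshots: 2}

rule:
  window: 5              # snapshots
  threshold: 0.30        # relative rise of the packing metric
  metric: mean_area      # mean_area | mean_volume | either
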