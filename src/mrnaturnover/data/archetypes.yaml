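# Default library of 16 gene-class archetypes for the heat-shock simulator.
#
# tr_shape: fold-change of TR relative to time 0 at each grid time
#           (first entry is always 1.0, the pre-shift steady state).
# kd_shape: fold-change of the decay constant k_D relative to its
#           steady-state value, one entry per inter-sample interval.
# stability / tr_direction: the designed ground-truth calls, used by
#           recovery tests; the shapes are chosen so the designed call
#           holds decisively over the whole kd0 sampling range.
#
# The classes span the qualitative behaviors seen genome-wide after a
# mild heat shock: a repressed branch (TR down, mostly destabilized,
# with varied timing), a transiently induced but destabilized branch
# (TR up, RA flat or down), and an induced branch (RA up, mostly
# stabilized), including purely post-transcriptional classes where RA
# rises with flat or falling TR.  Timing signatures (immediate step,
# ramp, pulse, dip-and-recover, delayed response) are deliberately
# varied so the classes are mutually distinguishable in profile space.
grid_times: [0.0, 4.0, 11.0, 16.0, 26.0, 40.0]
archetypes:
  - label: c01_tr_down_neutral
    tr_shape: [1.0, 0.80, 0.50, 0.40, 0.40, 0.45]
    kd_shape: [1.0, 1.0, 1.0, 1.0, 1.0]
    stability: unchanged
    tr_direction: down
    description: sustained TR repression, stability untouched, RA follows with a lag
  - label: c02_tr_late_down_destab
    tr_shape: [1.0, 0.95, 0.80, 0.55, 0.35, 0.25]
    kd_shape: [1.0, 1.1, 1.5, 2.2, 2.5]
    stability: destabilized
    tr_direction: down
    description: delayed progressive repression with late-building destabilization
  - label: c03_tr_step_down_destab
    tr_shape: [1.0, 0.25, 0.18, 0.16, 0.15, 0.15]
    kd_shape: [1.2, 2.0, 3.0, 3.5, 3.0]
    stability: destabilized
    tr_direction: down
    description: immediate strong TR shutoff plus accelerating destabilization (ribosomal-protein-like)
  - label: c04_tr_ramp_down_early_destab
    tr_shape: [1.0, 0.75, 0.45, 0.30, 0.18, 0.10]
    kd_shape: [3.5, 3.0, 1.8, 1.3, 1.1]
    stability: destabilized
    tr_direction: down
    description: progressive TR decline with an early destabilization spike (rRNA-processing-like)
  - label: c05_tr_dip_recover_destab
    tr_shape: [1.0, 0.30, 0.25, 0.45, 0.75, 1.0]
    kd_shape: [1.2, 2.0, 2.5, 2.0, 1.5]
    stability: destabilized
    tr_direction: down
    description: deep transient TR dip with full recovery, mid-course destabilization
  - label: c06_tr_down_early_destab_relax
    tr_shape: [1.0, 0.50, 0.35, 0.30, 0.28, 0.28]
    kd_shape: [3.0, 2.0, 1.0, 0.7, 0.6]
    stability: destabilized
    tr_direction: down
    description: repression with early destabilization relaxing into late stabilization, RA dips then recovers
  - label: c07_tr_spike_destab
    tr_shape: [1.0, 2.80, 1.60, 1.10, 0.95, 0.90]
    kd_shape: [2.5, 2.2, 1.5, 1.1, 1.0]
    stability: destabilized
    tr_direction: up
    description: sharp early TR spike cancelled by early destabilization, RA nearly flat
  - label: c08_tr_mid_pulse_destab
    tr_shape: [1.0, 1.05, 2.30, 1.90, 1.20, 0.95]
    kd_shape: [1.3, 2.2, 2.6, 1.8, 1.2]
    stability: destabilized
    tr_direction: up
    description: mid-course TR pulse cancelled by destabilization
  - label: c09_tr_ramp_up_destab
    tr_shape: [1.0, 1.40, 1.70, 2.00, 2.30, 2.50]
    kd_shape: [1.7, 1.9, 2.1, 2.3, 2.5]
    stability: destabilized
    tr_direction: up
    description: slow sustained TR rise matched by growing destabilization, RA stays near baseline
  - label: c10_tr_up_strong_destab
    tr_shape: [1.0, 2.20, 1.90, 1.60, 1.30, 1.20]
    kd_shape: [3.5, 4.0, 4.0, 3.8, 3.5]
    stability: destabilized
    tr_direction: up
    description: TR induction overwhelmed by strong destabilization, RA drops (antagonistic)
  - label: c11_tr_up_neutral
    tr_shape: [1.0, 2.50, 4.00, 4.20, 4.00, 3.80]
    kd_shape: [1.0, 1.0, 1.0, 1.0, 1.0]
    stability: unchanged
    tr_direction: up
    description: strong sustained TR induction, RA follows with kinetic delay only
  - label: c12_tr_pulse_stab
    tr_shape: [1.0, 3.50, 5.00, 2.50, 1.30, 1.05]
    kd_shape: [0.35, 0.30, 0.40, 0.60, 0.85]
    stability: stabilized
    tr_direction: up
    description: transient strong TR induction plus early stabilization (heat-shock-protein-like)
  - label: c13_tr_ramp_up_stab
    tr_shape: [1.0, 1.15, 1.60, 2.20, 2.80, 3.20]
    kd_shape: [0.75, 0.55, 0.40, 0.30, 0.25]
    stability: stabilized
    tr_direction: up
    description: slow TR ramp reinforced by deepening stabilization
  - label: c14_tr_step_up_stab
    tr_shape: [1.0, 3.00, 2.40, 1.90, 1.60, 1.50]
    kd_shape: [0.45, 0.45, 0.50, 0.55, 0.60]
    stability: stabilized
    tr_direction: up
    description: early TR step relaxing toward baseline with sustained stabilization
  - label: c15_tr_flat_stab
    tr_shape: [1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
    kd_shape: [0.35, 0.30, 0.35, 0.50, 0.70]
    stability: stabilized
    tr_direction: flat
    description: purely post-transcriptional induction, constant TR with transient stabilization
  - label: c16_tr_down_late_stab
    tr_shape: [1.0, 0.55, 0.45, 0.42, 0.40, 0.40]
    kd_shape: [0.9, 0.5, 0.3, 0.25, 0.25]
    stability: stabilized
    tr_direction: down
    description: TR repression outweighed by deepening stabilization, RA rises late (antagonistic)
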