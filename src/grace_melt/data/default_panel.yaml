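# Default GRACE-PCR alpha-globin panel.
# CLCN7 is the two-copy reference; HBA1/HBA2 are the targets.
# Product Tms are ~3 degC apart so each amplicon melts as a separable step.
# per_copy_amplitude is equal across amplicons: primer concentrations in the
# assay are balanced so the reference signal is comparable to the targets.
reference: CLCN7
reference_copies: 2
targets: [HBA1, HBA2]
allowed_copy_states:
  HBA1: [0, 1, 2, 3]
  HBA2: [0, 1, 2, 3]
amplicons:
  - {name: CLCN7, tm_c: 79.4, width_c: 0.2, per_copy_amplitude: 1.0, window_c: 1.2}
  - {name: HBA1, tm_c: 82.2, width_c: 0.2, per_copy_amplitude: 1.0, window_c: 1.2}
  - {name: HBA2, tm_c: 85.2, width_c: 0.2, per_copy_amplitude: 1.0, window_c: 1.2}
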