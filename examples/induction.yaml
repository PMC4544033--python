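# Induction time course: baseline vs 24 h / 48 h / 72 h of EMT induction,
# expressed as ground-truth fiber-density multipliers.
seed: 1
out_dir: run_induction
n_fields: 20
base:
  field_shape: [512, 512]
  n_nuclei: 8
  fibers_per_cell: 3.0
conditions:
  - {condition: control, multiplier: 1.0, time_h: 0}
  - {condition: tgf, multiplier: 7.0, time_h: 0}
quantify:
  min_cells: 100
  control_key: control
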