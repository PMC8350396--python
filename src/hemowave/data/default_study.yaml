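# Default three-state study configuration (healthy young adult baseline).
# Pressures mmHg, volumes mL, resistances mmHg.s/mL, compliances mL/mmHg.
scenario:
  banding_fraction: 0.80     # proximal aortic compliance reduction
  tpr_scale: 1.30            # peripheral resistance multiplier after banding
  vd_shift: -5.0             # acute dead-volume change, mL
  sv_target: null            # null = conserve the baseline stroke volume

heart:
  Ees: 3.2                   # end-systolic elastance, mmHg/mL
  Vd: 15.0                   # dead volume, mL
  P0: 2.3                    # EDPVR dead pressure, mmHg
  beta: 0.013                # diastolic stiffness, 1/mL
  Pfill: 11.5                # filling pressure, mmHg
  period: 0.8                # cardiac cycle, s (75 bpm; not stated by the
                             # study conditions, flagged in reports)
  t_systole: 0.3             # activation duration scale, s

tree:
  age: study-default         # study-default | 30 | 70  (CT 0.96 / 1.6 / 0.90,
                             # TPR 0.92 / 1.0 / 1.22)
  file: null                 # optional explicit tree YAML

solver:
  dx: 0.5                    # grid spacing, cm
  cfl: 0.9
  tol: 0.5                   # beat-to-beat convergence, mmHg
  max_beats: 30
  output_hz: 1000.0
  wall_damping: 0.0          # optional Voigt-type damping, cm^2/s
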