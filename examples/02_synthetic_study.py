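"""Generate a ground-truthed synthetic gait study.

One underlying knee motion per knee/trial is observed through five virtual
marker sets that differ by constant frame misorientations — the mechanism
that makes kinematic curves from different marker sets disagree even though
the motion is identical.
"""

import numpy as np

from reframe_gait import SyntheticConfig, build_study, compute_joint_angles

config = SyntheticConfig(n_subjects=2, trials_per_knee=3, rate_hz=100.0,
                         cycle_duration_s=1.0, seed=42).without_sta()
ds = build_study(config)
print(f"dataset: {len(ds)} trial records "
      f"({len(ds.marker_sets)} marker sets x {len(ds.knees())} knees x "
      f"{len(ds.trial_ids())} trials)")

truth = ds.truth[("S01", "S01_R", 1)]
for ms in ds.marker_sets:
    trial = ds.get("S01", "S01_R", 1, ms)
    observed = compute_joint_angles(trial.femur, trial.tibia)
    dev = np.abs(observed.gamma_deg - truth.gamma_deg).max()
    fem, tib = ds.misalignments[ms]
    print(f"{ms:12s} imposed fem z {fem[2]:6.1f}, tib z {tib[2]:6.1f} deg "
          f"-> max int/ext rotation deviation from truth {dev:5.1f} deg")
print("-> each marker set reports a different rotation curve for the same "
      "motion; the deviation tracks the imposed longitudinal misalignments.")
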