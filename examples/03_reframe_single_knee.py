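"""REFRAME on a single knee: recover an imposed frame misalignment.

A noise-free flexion-only motion is observed through frames rotated by known
constant offsets.  The optimizer searches for constant femoral and tibial
re-orientations minimizing RMS ab/adduction + RMS int/external rotation
+ 0.2 * flexion RMSE, and should cancel the imposed offsets.
"""

import numpy as np

from reframe_gait import ReframeConfig, cardan_xyz_to_matrix, optimize, rms

n = 101
s = np.linspace(0.0, 1.0, n)
alpha = -60.0 * np.sin(np.pi * s) ** 2  # flexion-only truth
T = cardan_xyz_to_matrix(np.column_stack([alpha, 0 * s, 0 * s]))

fem_mis = (1.0, 2.0, -6.0)   # imposed femoral frame misorientation, deg
tib_mis = (0.0, -3.0, 9.0)   # imposed tibial frame misorientation, deg
T_obs = cardan_xyz_to_matrix(fem_mis).T @ T @ cardan_xyz_to_matrix(tib_mis)

result = optimize(T_obs, alpha, ReframeConfig())
print(f"cost at identity  : {result.cost_initial:8.4f} deg")
print(f"cost after REFRAME: {result.cost_final:8.6f} deg "
      f"({result.n_evaluations} evaluations, converged={result.converged})")
print("femoral correction (x, y, z):", np.round(result.fem_triplet, 3))
print("tibial  correction (x, y, z):", np.round(result.tib_triplet, 3))
print(f"residual crosstalk: RMS add {rms(result.optimized.beta_deg):.2e}, "
      f"RMS rot {rms(result.optimized.gamma_deg):.2e} deg")
print("-> the corrections are close to the inverse of the imposed offsets "
      "(a shared rotation about the flexion axis is unobservable on a "
      "flexion-only motion), and the crosstalk channels collapse to zero.")
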