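"""Pairwise RMSE tables before and after REFRAME on a scaled study.

Runs the full pipeline on a small synthetic study and prints the mean +/- SD
RMSE matrix per angle channel for both stages — the raw table reflects the
imposed frame misalignments, the reframed table should collapse toward zero.
"""

from reframe_gait import ReframeConfig, RunManifest, SyntheticConfig, run_pipeline

config = SyntheticConfig(n_subjects=2, trials_per_knee=3, rate_hz=100.0,
                         cycle_duration_s=1.0, seed=5).without_sta()
manifest = RunManifest(reframe=ReframeConfig(), synthetic=config,
                       seed=config.seed, make_plots=False)
result = run_pipeline(manifest)

print(result.raw_table.render())
print()
print(result.reframed_table.render(fmt="{:.3f} ± {:.3f}"))
raw = result.raw_table.overall()
post = result.reframed_table.overall()
print(f"\nraw cells span {raw.mean_deg.min():.2f}-{raw.mean_deg.max():.2f} deg; "
      f"reframed max {post.mean_deg.max():.2e} deg")
print("-> the contraction shows the between-marker-set differences were "
      "frame-orientation artifacts, not genuine motion differences.")
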