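# Methods

## Kinematic model

Segment frames are right-handed with x lateral, y anterior and z proximal.
The joint rotation is the tibial frame expressed in femoral coordinates,
`T = R_femᵀ R_tib`, decomposed as an intrinsic X-Y-Z Cardan sequence
`T = Rx(α) Ry(β) Rz(γ)`: α is extension-positive (flexion negative; display
routines flip the sign), β adduction-positive, γ internal-rotation-positive.
The closed-form extraction is

```
β = atan2(T02, hypot(T00, T01)),  α = atan2(−T12, T22),  γ = atan2(−T01, T00)
```

with β restricted to [−90°, 90°]. Angles are stored in radians internally;
all public interfaces are in degrees. Channels are unwrapped per trial with a
180° jump threshold; gait signals are smooth, so this only guards against
branch flips that would otherwise inflate RMSE.

**Gimbal handling.** When |cos β| < 1e-7 the decomposition is degenerate and
a `GimbalLockError` is raised carrying the conventional resolution (γ := 0,
the free rotation folded into α) and the offending sample index. Knee
ab/adduction never approaches ±90°, so this signal indicates corrupt input
and is deliberately an error rather than a silent convention.

**Left knees.** Marker x-coordinates are inverted (points x ↦ −x, poses
R ↦ MRM, M = diag(−1,1,1)), which preserves det = +1, leaves α unchanged and
negates β and γ. The pose-level conjugation is unit-tested as equivalent to
rebuilding frames from mirrored markers with a toy frame recipe whose
mediolateral axis is derived as the cross product of the anteroposterior and
longitudinal axes. Containers track a `mirrored` flag and refuse double
mirroring.

## REFRAME optimization

The cost is a weighted **sum** of per-channel terms over the fitted series:

```
J = w_add·RMS(β) + w_rot·RMS(γ) + w_flex·RMSE(α, α_ref)      [degrees]
```

defaults 1 / 1 / 0.2, where α_ref is the reference marker set's raw flexion
(the reference set itself is optimized against its own raw flexion, so its
fitted corrections remain meaningful). The additive form follows from the
per-criterion weighting; it is configurable, so sensitivity to the
combination rule can be probed.

Corrections post-multiply each segment's orientation — they re-orient the
frame relative to the segment it represents — giving the corrected joint
rotation `R_femᵀ T_t R_tib` with the same constant pair for the whole series.
They are reported as intrinsic X-Y-Z Cardan triplets around the raw segment
axes.

**Femoral flexion-axis restriction.** Three semantics are provided:
`penalized` (x free, discouraged only through the flexion-RMSE term — the
default, because realistic fits do produce non-zero femoral x-corrections),
`locked` (x ≡ 0) and `bounded` (|x| ≤ limit, enforced by a steep quadratic
penalty).

**Optimizer.** Deterministic Nelder-Mead over the 4–6 correction parameters
(degrees). Starts: identity plus the best points of a fixed lattice over the
out-of-sagittal (y/z) parameters, ±12° in 6° steps, evaluated in a vectorized
batch; the best of the restarts is polished by a second small-simplex run.
An explicit initial simplex (2° edges; 0.05° for the polish) is supplied
because the default simplex around a zero start is ~2.5e-4° wide and crawls.
Termination at cost change ≤ 1e-8 (deg) within 10 000 evaluations per start;
non-convergence is reported on the result (`converged=False`), never
silently. The landscape is smooth; the lattice guards against the local
minima that large longitudinal offsets can create.

**Identifiability.** On a flexion-only motion the cost is invariant under a
shared extra rotation of both frames about the flexion axis, so per-segment
corrections are determined only up to that common rotation. The well-posed
quantity is the composed joint-level residual
`R_femᵀ M_femᵀ M_tib R_tib` (correction composed onto imposed misalignment),
which parameter-recovery checks drive to identity within 0.1° per axis.

**Fitting unit.** Default: one correction pair per knee per marker set,
fitted on that knee's trials concatenated after cycle normalization
(per-trial fitting is available via `fit_per_trial`). Fitting across trials
stabilizes the estimate and matches the idea that a frame misorientation is
a property of the marker placement, not of a single step.

## Comparison metrics

RMSE between equal-length waveforms and RMS (RMSE against constant zero) are
computed per trial on cycle-normalized waveforms, then aggregated two ways:
mean ± SD per knee across its trials, and overall across all trials and
knees (the overall level pools trial-level values rather than averaging knee
means; sample SD, ddof = 1; size-1 groups report SD 0 with a warning flag).
The pairwise table holds one cell per ordered marker-set pair and channel.
RMSE itself is symmetric; rendering raw and reframed stages into opposite
triangles of one matrix is presentation only.

## Cycle normalization

Public angle-series normalization resamples each cycle to 101 points on
0–100 % by linear interpolation of the unwrapped channels (community
convention for gait waveforms). The pipeline instead resamples the joint
*rotation* series to the same grid by spherical interpolation (Slerp), then
extracts angles; Slerp commutes with constant frame corrections
(`slerp(A R B) = A slerp(R) B`), so raw and reframed waveforms live on
exactly the same footing and the reframed table is not polluted by
interpolation asymmetry. At 100–200 Hz the difference between the two
schemes is far below 0.01°.

## Synthetic study generator

The generator emulates a treadmill-gait study: 15 subjects × 2 knees × 9
steps at 200 Hz (~1.1 s cycles), observed through 5 virtual marker sets.
Ground truth is a smooth periodic motion: flexion built from two von-Mises
bumps (stance wave ≈ 20°, swing peak ≈ 60°) projected onto 12 Fourier
harmonics; ab/adduction and int/external rotation are low-harmonic waveforms
with a few degrees' amplitude. All channels are anchored to zero at the
cycle start, so the joint rotation at heel strike is exactly the identity —
this makes the zero-flexion crosstalk prediction exact. Per-trial
variability scales channel amplitudes by N(1, 0.03). Each subject's second
knee is generated in left-side coordinates and passed through the mirroring
step, exercising that code path end to end.

Each marker set applies a constant misorientation (Cardan triplet per
segment) patterned in magnitude on reported between-marker-set
transformations — longitudinal offsets up to ~15°, a few degrees elsewhere.
These presets are configuration, not claims about any real system. An
optional soft-tissue artifact adds a zero-mean rotation about a random fixed
axis per segment and trial, with amplitude (default 0.5°) following the
flexion waveform (coupling 0.5) plus low-frequency noise; it is deliberately
simple and switchable off (`SyntheticConfig.without_sta()`), since constant
corrections cannot remove time-varying frame motion and the pass/fail
criteria are defined for the constant-misalignment regime.

What passing tests on this generator show: that the implementation recovers
constant frame misorientations exactly and that the full pipeline contracts
between-marker-set RMSE to numerical zero when the generative assumption
(constant misalignment) holds. What they do not show: behavior under real
soft-tissue artifact patterns, marker occlusions/gap-filling, event-detection
errors, or non-rigid segment models — real data violate the constant-frame
assumption to varying degrees, and residual post-alignment differences there
are expected and informative.

## Numerical choices

- Rotation validation: orthonormality and det = +1 within 1e-9.
- Cardan round-trip accuracy ≤ 1e-9 degrees away from the gimbal zone.
- Pipeline problem sizes: the shared test study uses 2 subjects × 2 knees ×
  3 trials at 100 Hz; the study-level convergence checks and the acceptance
  script run the full 15-subject design.
- Determinism: all randomness flows from a single integer seed through
  `numpy` `SeedSequence` spawning; a saved run manifest replays to
  byte-identical numeric outputs.

## Known limitations

- Rotations only: frame *origin* (translational) alignment is out of scope.
- Corrections are constant per fit; time-varying misalignment (soft-tissue
  artifact) biases rather than breaks the fit and leaves residual
  disagreement.
- The cost uses degree-scaled RMS sums; channels are not variance-normalized.
- The flexion reference couples all marker sets to one dataset's flexion
  curve; a poor reference propagates into every fit.
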