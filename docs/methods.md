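# Methods

## Task model and coordinate conventions

The displacement task is encoded as design constants: fixation at 6 or 8°
on one side of the screen, target at 6 or 8° on the other, giving stimulus
amplitudes of 12, 14 or 16°; a variable foreperiod of 1600–2400 ms; a 5-s
response window; blocks of 24 trials with 5–6 blocks per condition and a
fixed saccade direction per block. Displacements are controlled by three
independent one-up-one-down staircases with constant step size 3° (STEP)
or 1.5° (BLANK), starting at +7/0/−7° and +3.5/0/−3.5° respectively. Each
staircase is confined to its own lattice `start + k·step`; because the
starts' residues modulo the step cover all residue classes, the union of
the three lattices samples the displacement axis at 1° (STEP) and 0.5°
(BLANK).

All analysis-facing quantities (displacement, PSS, targeting error) are
expressed *forward-positive* relative to the saccade direction; screen
coordinates (rightward-positive) appear only in raw trial records. This
single internal frame avoids the sign errors that arise when leftward and
rightward blocks are mixed.

Choices on points the task description leaves open: staircase assignment
per trial is a seeded random interleave balanced to ±1 trial per
staircase; fixation and target eccentricities are drawn independently and
uniformly; void trials (no response within 5 s) leave the staircase level
unchanged and are excluded from fitting.

## Observer model

The generative observer is the smallest linear model that realizes three
mechanisms of CD-based perceptual stability, one parameter each:

* execution: `S = g·|A| + ε_m`, `ε_m ~ N(0, σ_m²)`, with motor gain `g`
  (default 0.92, between typical leftward/rightward gains of 0.90/0.94)
  and motor noise `σ_m` (default 1.0°, matching targeting-error SDs of
  roughly 0.9–1.1°);
* monitoring: `Ŝ = g_cd·(g·|A| + λ·ε_m) + ε_cd`. The CD gain `g_cd`
  (1 = veridical) scales the internal amplitude estimate; a hypometric CD
  (`g_cd < 1`) underestimates it by `(1 − g_cd)·g·|A|` ≈ 1.3° at 14° for
  `g_cd = 0.9`, which is the size of forward PSS shifts seen in lesion
  cases. The coupling `λ ∈ [0, 1]` is the fraction of the trial's motor
  error captured by monitoring; `λ = 1` cancels `ε_m` out of the percept
  entirely, `λ = 0` leaks it in with full weight;
* decision: `D̂ = D + (Ŝ − S)`; report forward iff `w_cond·D̂ + ε_dec > 0`
  with condition-specific decision noise. Saccadic suppression of
  displacement is modeled as `σ_dec,STEP > σ_dec,BLANK` (defaults 2.0° vs
  0.5°, chosen so that simulated control thresholds land near 1.3–1.6° in
  STEP and 0.3–0.6° in BLANK, the range healthy adults produce); the
  reliance weights `w` are exposed but default to 1. A small lapse rate
  (0.02) replaces the report with a coin flip.

Presets: `control_preset()` (intact: `g_cd = 1, λ = 1, σ_cd = 0.3°`) and
`thalamic_preset()` (`g_cd = 0.9, λ = 0, σ_cd = 0.6°`). They are
illustrative parameter points, not fits to any patient. Lateralized
deficits are simulated by giving each saccade direction its own parameter
set.

What the simulator does *not* emulate: blinks, drift, smooth pursuit,
intrasaccadic motion percepts, learning or fatigue across blocks, and any
nonlinearity in the CD transform. Passing tests therefore demonstrate that
the analysis chain recovers the planted mechanisms under idealized
conditions, not that real patient data would be this clean.

## Eye traces and saccade detection

Synthetic traces are sampled at 500 Hz: ≥200 ms pre-saccadic and ≥250 ms
post-saccadic fixation around a raised-cosine velocity pulse whose
duration follows `T = 2.2·|amp| + 21` ms (≈52 ms at 14°, peak velocity
≈540°/s). Additive Gaussian position noise models tracker noise. Because
a raised cosine leaves zero velocity smoothly, the 30°/s criterion is
crossed ~4 ms after motion onset; traces therefore expose two ground-truth
timestamp pairs — the motion interval (position change equals the executed
amplitude exactly) and the analytic 30°/s crossings (what a
velocity-criterion detector should report). Detector round-trip tests use
the crossing times; construction tests use the motion interval.

Detection low-pass filters positions with a zero-phase second-order
Butterworth at 60 Hz (configurable; the cutoff preserves the ~20–40 Hz
content of the velocity pulse, peak velocity to within ~2%), computes
velocity by central differences, and applies the fixed 30°/s criterion.
With several suprathreshold intervals (corrective saccades) the
largest-displacement interval is returned and the event flagged. Start and
end positions are medians over 50-ms fixation windows. Trials whose
detected saccade opposes the instructed direction, or lack a landing, are
excluded from aggregates and counted.

Error conventions: `targeting_error = executed − |A|` (undershoot
negative) for oculomotor summaries; `hypometria_error = −targeting_error`
(hypometric positive) for the error-attribution analysis.

## Psychometric fitting and thresholds

`P(forward|d) = lapse/2 + (1 − lapse)·Φ((d − PSS)/JND)` is fit by
maximizing the Bernoulli likelihood with L-BFGS-B in `(PSS, log JND)` from
five deterministic starts (level quantiles × spread fractions); JND is
bounded to [10⁻³, 50]° and fits at a bound are flagged. The lapse is fixed
at 0 by default with optional bounded estimation in [0, 0.05]. Degenerate
data (all responses identical, <2 levels) raise errors rather than
returning numbers.

Percent correct folds the fitted curve:
`PC(|d|) = [F(|d|) + 1 − F(−|d|)]/2`, defined for `|d| > 0` only (null
displacements carry no correct answer and are discarded). The perceptual
threshold is the smallest `|d|` with `PC = 0.75`, found by bracketed root
finding to 10⁻⁴ °; with zero bias it equals `0.6745·JND`. The threshold is
read off the fitted function, not raw binned proportions, because at
~120 trials per cell the fitted-curve threshold is substantially more
stable; this is an interpretation choice where the procedure could also be
read as thresholding raw percent-correct points.

## Deficit measures and classification

Per subject and direction: the relative threshold BLANK/STEP (blanking
benefit), the BLANK threshold asymmetry (rightward − leftward), and the
error-attribution correlation — BLANK trials sorted by hypometria error
into 8 equal-count bins (remainder to the lowest-error bins), Pearson
correlation between bin mean error and bin forward-report proportion with
df = 6. Classification uses control-sample norms: relative threshold is
one-sided (impaired above mean + 1.96 SD — only a *missing* benefit is
abnormal), asymmetry two-sided (±1.96 SD), attribution by p < 0.05 with
positive r. Boundary equality is not impaired. No multiple-comparison
correction is applied across measures or directions, matching standard
practice for these individual-case criteria.

## Lesion-symptom mapping

Per voxel the cohort yields a 2×2 table of impairment × lesion status. The
Liebermeister quasi-exact test increments both concordant cells and takes
the upper hypergeometric tail: `p₁(a,b,c,d) = P(X ≥ a+1)` for
`X ~ Hypergeom(n+2, a+1+b, a+1+c)`. This equals the Bayesian posterior
probability `P(θ_lesioned ≤ θ_spared | data)` under independent uniform
priors — verified exhaustively against a numerical double-integral oracle
for all tables with n ≤ 12 (agreement ≤ 10⁻⁸) — and is uniformly less
conservative than Fisher's exact test. Maps are one-sided in the
lesion→impairment direction (z > 0 means lesion associated with
impairment), uncorrected at α = 0.05 by default with an optional
Bonferroni flag; only voxels lesioned in ≥2 patients are tested. The power
map reports, per included voxel, the p-value attainable if lesion status
aligned perfectly with the behavioral split; the significant set is always
contained in the powered set. The peak is the maximal-z voxel; exact ties
(identical contingency tables) are broken by the tied voxel nearest the
tie set's center of mass. Cluster size counts the 26-connected
suprathreshold component at the peak.

The synthetic cohort plants a compact 2×2×2-voxel critical region
(64 mm³ at 2-mm voxels — the scale of a small intralaminar nucleus
cluster) whose center voxel maps to (8, −15, 4) mm under the MNI-like
affine. Patients receive one axis-aligned ellipsoidal lesion (radii
2–4 voxels) centered uniformly in a vascular-territory box around the
region, sized so that roughly half of a 14-patient cohort overlaps the
region — the impaired fraction observed in real thalamic samples. Labels
equal the overlap indicator, optionally flipped with a noise probability;
cohorts are redrawn until ≥2 patients are lesioned inside the region and
both labels occur. A block atlas (critical nucleus plus three neighboring
blocks) supports the nucleus-level chi-square association.

## Pipeline and problem sizes

The default pipeline simulates 8 controls + 3 patients at 5 blocks per
condition (120 trials per condition × direction), regenerates and
re-detects eye traces for 48 trials per subject as a detection audit, fits
4 cells per subject, classifies against the control norms, and maps a
14-patient synthetic lesion cohort; it completes in a few seconds on one
CPU. Acceptance-style simulations use 600–2000 trials per observer, 100
seeds for recovery studies and 10 seeded cohorts for recovery rates —
sizes at which the Monte-Carlo assertions are stable while the whole suite
runs in about a minute. All stages derive their seeds deterministically
from the configured base seed, and every output table records the seed and
configuration hash.

## Known limitations

* The observer is linear and stationary; it cannot express partial,
  direction-tuned CD damage within one block type (only via per-direction
  parameter sets).
* JND estimates at session size (~120–144 trials) carry the usual MLE
  small-sample bias (a few percent low); thresholds inherit it.
* The behavioral simulation and the lesion cohort are generated
  independently — the pipeline's VLSM stage is a self-contained recovery
  demonstration, not a link from simulated behavior to simulated anatomy.
* Lesion masks are axis-aligned ellipsoids on a 32³ grid; real lesion
  geometry, spatial normalization error and atlas co-registration are out
  of scope (the package consumes pre-labeled masks).
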