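# transsacc

Analysis and simulation toolkit for **trans-saccadic displacement
perception** and its disruption after focal thalamic lesions.

When the eyes move, the image of the world sweeps across the retina, yet
perception stays stable. A leading account is that an internal copy of the
oculomotor command — a *corollary discharge* (CD) — lets the visual system
predict and discount the self-generated change. The classic probe is the
intrasaccadic displacement task: a saccade target jumps in sync with the
eye movement and the subject reports the apparent jump direction. Jumps
that occur during the saccade are hard to see (*saccadic suppression of
displacement*), but briefly blanking the target (250 ms) restores high
sensitivity. Lesion patients whose CD pathway is damaged lose this blanking
benefit, show direction-specific biases, and misattribute their own
saccade targeting errors to external jumps.

`transsacc` implements the full analysis chain for this paradigm, runnable
end-to-end on simulated cohorts:

- **task engine** — task geometry (6/8° fixation and target eccentricities,
  12/14/16° stimulus amplitudes), three randomly interleaved one-up-one-down
  staircases (step 3° STEP / 1.5° BLANK, starts ±7/0° and ±3.5/0°) sampling
  displacement at 1° / 0.5° resolution;
- **observer model** — a minimal linear CD observer. Saccade execution
  `S = g·|A| + ε_m`; internal estimate `Ŝ = g_cd·(g·|A| + λ·ε_m) + ε_cd`;
  perceived displacement `D̂ = D + (Ŝ − S)`; report forward iff
  `w·D̂ + ε_dec > 0`. One parameter per mechanism: `g_cd < 1` (hypometric
  CD) produces a forward shift of the psychometric function, `λ < 1` breaks
  trial-by-trial error monitoring (error misattribution), and
  `σ_dec,STEP > σ_dec,BLANK` encodes saccadic suppression;
- **oculomotor** — synthetic 500-Hz gaze traces (raised-cosine velocity
  pulse), zero-phase low-pass filtering, 30°/s velocity-criterion saccade
  detection, amplitude gain and signed targeting errors;
- **psychometrics** — maximum-likelihood cumulative-Gaussian fits
  `P(forward|d) = λ/2 + (1−λ)·Φ((d − PSS)/JND)`, folding into percent
  correct, and the 75%-correct displacement threshold;
- **deficit profiling** — relative threshold (BLANK/STEP), right−left
  threshold asymmetry, 8-bin targeting-error/report correlation, each
  classified against control norms at ±1.96 SD;
- **vlsm** — voxel-based lesion-symptom mapping on NIfTI masks: overlap
  and 15%-thresholded subtraction maps, voxelwise Liebermeister quasi-exact
  tests restricted to voxels lesioned in ≥2 patients, power maps, and
  nucleus-level chi-square association.

## Worked example

```sh
transsacc all --seed 1 --out runs/demo
```

simulates 8 controls and 3 lesion-like patients (two with a unilateral,
one with a bilateral CD deficit), fits every condition × direction cell,
classifies deficits and maps a synthetic 14-patient lesion cohort. The
report printed for seed 1 ends with:

```
Simulated cohort thresholds (deg, per condition x direction)
condition    BLANK               STEP
direction leftward rightward leftward rightward
subject
C01          0.530     0.595    1.188     1.537
...
P01          1.392     0.482    1.939     1.013
...
Lesion-symptom mapping (synthetic cohort, planted critical region)
  voxels tested: 401, significant at alpha=0.05: 49
  peak voxel (21, 7, 16) at (10.0, -19.0, 4.0) mm, cluster size 49 voxels
```

Controls detect ~0.3–0.6° displacements after blanking but need ~1.1–1.9°
in the STEP condition — the blanking benefit. Patient P01 (leftward CD
deficit) loses the benefit for leftward saccades only (1.39° vs 0.48°
rightward), is flagged on the relative-threshold, asymmetry and
error-attribution measures, and the lesion map's peak z voxel falls next
to the planted critical region (reported in MNI-like mm coordinates).

The same stages are available as library calls (`simulate_session`,
`fit_condition_thresholds`, `cohort_profiles`, `vlsm_map`, ...) and as
individual CLI verbs (`simulate`, `fit`, `profile`, `vlsm`).

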