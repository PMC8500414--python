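# Methods

This note records the models, parameter choices and numerical
conventions behind `trajerp`, and what the synthetic validation does
and does not establish about real recordings.

## Paradigm model

Positions are indexed 0–11 clockwise from 12 o'clock; 30° per slot.
The cued shape starts at `start_position` and advances one slot per
step in the rotation direction; the non-cued shape is anchored so that
its final slot lies three slots clockwise of the cued shape's final
slot. In unpredictable sequences the condition-designated lateral
shape repeats its step-4 slot at step 5 (the "moved back one position"
violation) while the other shape continues; consequently the two
shapes' separation during steps 1–4 is 3 ± 1 slots depending on
rotation, settling to 3 at the final display. The arrow always points
at the cued shape's trajectory-implied slot, so only in
`unpredictable_cued` sequences does it point at an unoccupied position
(at step 5).

Endpoint geometry: the lateral shape's final slot is constrained to
the strictly lateral positions 3 (right visual field) or 9 (left), and
the midline shape lands on 0 or 6. Strict laterality makes the
contralateral-hemisphere mapping unambiguous; which slots count as
"lateral" is otherwise a free design choice and is configurable only
by editing `paradigm.LATERAL_SLOT`. Pixel geometry (225 px shapes,
12 px dots, visual angles) is carried as metadata; nothing is
rendered.

Balancing: each condition's sequences split exactly evenly over
rotation (2) × endpoint visual field (2); the cued shape alternates
circle/square, giving 54/54 within a 108-sequence condition and a
13/14 split within a 27-sequence cell — the triple cross cannot be
exact at these counts and is reported, not forced. Red-dot vigilance
sequences are drawn evenly from the four conditions (12 each at the
default 48), carry their dot on a uniformly random step, and are
discarded before any averaging. Presentation order is a seeded
permutation; identical seeds are bit-reproducible.

## Synthetic EEG model

Each epoch holds two channels — the pooled left- and right-hemisphere
occipito-temporal clusters — on a −2100…+500 ms axis (t = 0 at the
final stimulus onset; step k onset at (k−5) × 500 ms), sampled at
256 Hz by default (configurable; desk-scale speed is the only reason
it is below a hardware-typical 1024 Hz). Components are Gaussian bumps
parameterised by peak latency, FWHM and signed peak amplitude: P1
(+, 100 ms, 30 ms), N170 (−, 175 ms, 35 ms), N2pc (−, 250 ms, 100 ms
FWHM, i.e. 50 ms half-width, sitting inside the 200–300 ms analysis
window). Steps 1–4 evoke bilateral base-amplitude P1+N170 responses;
the final step adds the condition-dependent N170 bilaterally and the
condition-dependent N2pc **only** on the channel contralateral to the
endpoint visual field. These are phenomenological waveform models, not
dipole projections, and only pooled clusters are simulated because the
analysis never touches unpooled electrodes.

Amplitudes are specified on the scale on which they are analysed and
calibrated so that the noiseless pipeline measures exactly the
configured targets:

* `n170_amplitude` = grand-mean peak-to-peak N170 (−2.155 µV, the
  average of the four cell means implied by the reported marginals);
  expectation (−0.27 µV) and cueing (−0.21 µV) effects split ± half
  around it. The required template peak per condition is solved by
  fixed-point iteration against the measured peak-to-peak of the
  pooled waveform, which also absorbs the small leakage of the pooled
  contralateral N2pc into the 140–210 ms window.
* `n2pc_amplitude` = grand-mean 200–300 ms window mean of the
  difference wave (+0.045 µV; +0.19 predictable, −0.10 unpredictable,
  expectation effect −0.29 µV, no cueing effect). Template peak =
  target / (window mean of the unit template). Bilateral components
  cancel exactly in the contra-minus-ipsi difference, so no further
  correction is needed.

Between-subject structure: additive Gaussian shifts on each
component's amplitude (SD 0.5 µV P1, 1.25 µV N170 peak-to-peak,
0.2 µV N2pc) plus Gaussian random *slopes* on each injected effect
(SD 0.46 µV N170-expectation, 0.28 µV N170-cueing, 0.47 µV
N2pc-expectation). Noise is white (3 µV per sample) plus
spectrally-shaped 1/f noise (4 µV RMS), independent across epochs and
channels. These six numbers were derived once from the reported
summary statistics: the noise level leaves the reported per-cell
standard errors attainable (~0.2 µV N170, ~0.1 µV N2pc at n = 36), and
each slope SD is solved from the corresponding reported F value given
the measurement-noise contribution, so the expected F statistics at
n = 36 are ≈ 8.7, 7.7 and 4.9. Without random slopes every subject
would share identical effects and all F values would diverge; a single
between-subject SD cannot satisfy both the cell SEs and the Fs, which
is why the single "amplitude variability" knob became per-component
and per-effect SDs. No latency jitter by default (amplitude effects
are the only reported quantities); an optional subject-level jitter SD
exists. Blink artifacts are square pulses (800 µV, 200 ms, 2 % of
epochs) sized to trip min-max rejection.

What the generator does **not** emulate: 64-channel topography, real
ocular/EMG artifact morphology, autocorrelated trial-to-trial drifts,
latency variability across subjects, or any violation of the additive
Gaussian model. Passing recovery tests therefore shows the *pipeline*
is unbiased and calibrated under the stated generative assumptions;
it cannot certify behaviour under artifact structures the generator
does not produce.

## Preprocessing conventions

* "24 dB/octave" is read as a 4th-order Butterworth (order =
  rolloff/6), applied forward–backward (`sosfiltfilt`), which doubles
  the effective rolloff — the zero-phase convention of mainstream ERP
  software. The 50 Hz notch is a Q = 30 IIR notch, also zero-phase.
  Filtering attenuates the measured peak-to-peak N170 by ~0.04 µV
  uniformly across conditions (checked in tests); condition
  differences are preserved to < 0.002 µV.
* Min-max rejection slides its 100 ms window sample-by-sample (stride
  1), the stricter reading of "100 ms intervals"; disjoint blocks
  would be blind at block boundaries. Bad spans are padded ± 100 ms
  and any epoch containing one is dropped whole; kept epochs are never
  modified.
* Average re-reference is an explicit pass-through on the two pooled
  channels (subtracting the cross-channel mean would destroy the very
  lateralisation the N2pc measures); with a full montage (> 2
  channels) the stage subtracts the cross-channel mean.
* Baseline: the scalar mean over the pooled samples of two windows —
  [−650, −500] and [−150, 0] ms, i.e. [−150, 0] relative to both the
  step-4 and step-5 onsets — is subtracted per epoch and channel
  (idempotent). This dual-window form exists because the paradigm has
  no inter-stimulus interval.

## Measurement conventions

P1 = sample-wise maximum in 80–130 ms, N170 = minimum in 140–210 ms,
ties broken by the earliest sample, no parabolic interpolation; window
endpoints are inclusive at sample resolution (configurable). The
stated component polarities ("N170 maxima", "P1 minima" in some
descriptions of peak-to-peak measurement) are internally inconsistent;
peak-to-peak = N170 minimum − P1 maximum is the reading that
reproduces negative reported means and is what this package computes.
N170 measures use the average pooled over both hemispheres and both
visual fields per condition; the N2pc difference wave is contra −
ipsi per visual field (left VF → right hemisphere), pooled by
pointwise mean over the two VFs.

## Statistics

The 2×2 within-subject ANOVA is computed from per-subject contrast
scores; each effect is tested against its own subject × effect error
term (F = paired t², df = (1, n−1)), sphericity holds automatically
with two-level factors, and ηp² = F/(F + n − 1) ≡
SS_effect/(SS_effect + SS_error). Zero error variance yields F = ∞
with a warning rather than an exception. Cook's distance defaults to
an intercept-only model on each subject's cell mean (closed form:
D_i = r_i² h/( s²(1−h)²), h = 1/n), with a switch to screen on any
single effect's contrast scores instead; D > 4/n is flagged, nothing
is auto-excluded — the model behind the published screening is not
specified, so the choice is exposed rather than hidden.

Cluster test conventions: the height threshold is the exact two-tailed
critical t (2.0301 at df = 35, not the rounded 2.02 sometimes quoted);
cluster membership requires constant sign in addition to |t| above
threshold (a sign change splits a supra-threshold run, standard
cluster-permutation practice); minimum cluster length is 1 sample
(singletons are harmless under a max-statistic null) and configurable;
sign-flip patterns identical to the observed labelling are included
(each subject flips with probability ½, so the identity pattern has
probability 2⁻ⁿ like any other); observed clusters are compared to the
null as |summed t|, making the criterion two-tailed; p = (1+b)/(1+B)
avoids zero p-values. Permutations are evaluated in vectorised blocks:
sign flips leave per-subject squared values unchanged, so all permuted
t-series come from one matrix product, and per-permutation maximal
cluster values from run-boundary bookkeeping (`np.add.reduceat`); the
fast path is property-tested against the scalar cluster former. Both
cluster contrasts (expectation and cueing) are run on the N2pc
difference waves over −100…500 ms, matching the waveforms of the main
analyses. Exhaustive enumeration of all 2ⁿ sign patterns replaces
Monte-Carlo sampling on request (n ≤ 20).

## Validation design and problem sizes

The reference statistics were computed on non-public recordings, so
validation is structural and statistical rather than numeric
reproduction: design arithmetic of the session plan (exact); ANOVA
against the paired-t identity and a statsmodels oracle; Monte-Carlo
vs exhaustive permutation nulls at n ≤ 12; family-wise type-I error of
the cluster test in [0.03, 0.08] over 500 null datasets (n = 20, 601
samples, 800 permutations each); recovery of the injected −0.27,
−0.21 and −0.29 µV effects within 2 Monte-Carlo SEs over ten replicate
36-subject cohorts; and the qualitative result pattern (significant
expectation cluster overlapping 200–300 ms, no cueing cluster, N170
main effects without interaction) on strong-effect cohorts
(N2pc expectation effect −0.8 µV), judged by majority over three
cohorts so the check reflects the pattern rather than a single noise
draw. These sizes keep the whole suite around a minute on one CPU
while leaving Monte-Carlo error well inside the tested tolerances.

## Known limitations

* Epoch CSVs in long format are bulky (~10⁶ rows per subject at
  256 Hz); `run_pipeline` therefore keeps epochs in memory and writes
  them only on request (`write_epochs=True`, or the `simulate`
  subcommand whose purpose is producing the files).
* The acceptance-style F statistics of a single simulated cohort are
  stochastic by design; only their expectations are calibrated.
* The BioSemi/BDF import adapter is an extension point, not
  implemented; the pipeline consumes the documented long-format epoch
  CSV (or in-memory `EpochSet` objects).
* ICA ocular correction and spherical-spline channel interpolation are
  real-data housekeeping outside this package's scope; threshold-based
  rejection substitutes for them on synthetic data.
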