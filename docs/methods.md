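# Methods

This note documents the models, parameter choices and numerical decisions
behind `qcucvp`, and what the synthetic-data tests do and do not establish
about real captures.

## Measurement principle

A vein collapses when the pressure outside its wall exceeds the pressure
inside. Pressing an instrumented ultrasound probe over the internal jugular
vein (IJV) raises the external tissue pressure roughly in proportion to the
applied force; the force at which the short-axis lumen falls below an
occlusion threshold of 0.5 mm² — the collapse force, CF — therefore encodes
the venous pressure at the site. Correcting for the hydrostatic column
between the measurement site and the right atrium (HO = 10·sin θ cmH₂O for
bed inclination θ, under a fixed 10 cm site-to-atrium distance) relates the
site pressure to central venous pressure (CVP). Pressures convert between
cmH₂O and mmHg with C = 0.7356 mmHg/cmH₂O.

## Collapse-force extraction

**Detection.** CF is the force at the *first* ramp sample whose segmented
IJV area is below the 0.5 mm² threshold (a minimum-force definition; ties
break toward earlier time). A capture already occluded at ramp start is
rejected as "pre-collapsed"; a ramp that never occludes raises "no collapse
detected".

**Uncertainty.** The area under the probe swings with the cardiac cycle
(period < 1 s, right-atrial morphology) and with respiration (period > 1 s,
near-sinusoidal). The vein would have collapsed earlier had the pressure
been at its trough throughout, and later at its crest; the CF interval
quantifies this. Over a window before the detected collapse (default 5 s —
long enough to sample a full respiratory period at typical rates), the
per-cardiac-cycle minima and maxima of the area are collected, blocks
anchored at the collapse end. Near collapse the compressed lumen shrinks
exponentially with force, so extrapolation is done in log-area coordinates,
where the trend is straight: a single compression slope d(log A)/dF is
fitted on the final 2 s before collapse, the two envelope lines share that
slope with intercepts set by the extreme per-cycle residuals (restricted to
genuinely compressed points — those below 60% of the window's area maximum —
because points near the relaxed-area ceiling carry no force information),
and the forces where the lower/upper envelope line crosses the threshold
give cf_lo/cf_hi. Bounds are clipped to [0, max ramp force] with a warning
when an extrapolated crossing leaves the recorded ramp. With all
physiological variation disabled the two envelopes coincide with the area
curve itself and the interval collapses to the point estimate — the contract
that fixed the choice of log-area coordinates.

## Calibration and agreement

Fits are ordinary least squares of average invasive CVP on CF, optionally
with HO (always converted to mmHg before entering a design matrix — the
convention that reproduces the study table's derived columns). At least
p+1 complete records are required for p predictors; with exactly p+1 the
fit interpolates and coefficient t-tests are undefined. Reported metrics:
coefficient two-sided t-test p-values, r², mean absolute error, and the
sample standard deviation (n−1) of the signed error about its mean — the
convention that uniquely reproduces all three published SD-of-error values
(1.24, 1.88, 2.17 mmHg). JVP agreement is computed on the raw JVP pressures
against invasive CVP (the identity-line reading), not on a regression of
them. The previously trained model is applied as the fixed affine rule
0.42·CF + 0.054 + HO(mmHg); its published coefficients are rounded, so
per-subject agreement with previously published estimates is expected only
to a few hundredths of a mmHg.

## Uncertainty intervals and overlap accuracy

Four uncertainty sources: (1) the CF interval, pushed through the fitted
calibration so it lives in predicted-CVP units; (2) a fixed ±0.5 mmHg
hydrostatic term (angle imprecision and anatomical variation in the 10 cm
distance), added whenever HO participates in a model; (3) ±0.5 mmHg on JVP
readings (repeatability plus whole-number height rounding); (4) the invasive
measurement's own respiratory variation, quantified as ±2 standard
deviations of the low-pass-filtered waveform. A method "hits" a subject
when its interval contains the invasive scalar — deliberately a
point-in-interval test, without the invasive uncertainty. Force-based
methods exclude subjects measured on an external jugular (thrombosed IJV);
the JVP statistic counts attempted-but-unreadable subjects as forced misses
and drops never-attempted subjects. On the bundled table this yields
denominators of 9 for the force methods and 5+3 for JVP.

## Signal processing

The cardiac/respiratory boundary is 1 Hz, realized as an order-8 Butterworth
low-pass applied forward-backward (`sosfiltfilt`, zero phase; the effective
magnitude response is squared, attenuating a 1.2 Hz tone by ~95% while
passing 0.25 Hz essentially unchanged). The respiratory component retains
the mean; the cardiac component is the residual. Respiratory SD is the
standard deviation of the respiratory component, A/√2 for a sinusoid of
amplitude A.

Force/frame synchronization exploits the quick compressions at the start
and end of each acquisition: both channels are high-passed above the band
boundary, force transients are localized (they must clear both half the
channel maximum and six robust standard deviations, so sensor noise alone is
"unsyncable"), and cross-correlation restricted to those neighborhoods and
to lags within ±2 s gives the offset; the sign convention is the time by
which the area channel lags the force channel. The neighborhood restriction
keeps ongoing cardiac pulsation in the area channel from dominating the
correlation.

## Collapsible-tube model

The forward model maps (venous pressure, carotid pressure, probe force) to
(IJV area, carotid area):

* transmural pressure p = p_ijv − p_ext, with
  p_ext = transmission·force/contact_area (converted to mmHg;
  1 N/cm² = 75.006 mmHg) + κ·(p_carotid − carotid reference);
* collapse branch (p ≤ 0): A = a_ref·exp(n_neg·p/k);
* distension branch (p > 0):
  A = a_ref·(1 + (1 − exp(−n_pos·n_neg·p/k))/n_pos), joining with continuous
  slope at p = 0 and saturating at a_ref·(1 + 1/n_pos);
* carotid area: linear compliance about its reference pressure.

The exponential collapse branch was chosen over a Shapiro-type power law
with the classic −3/2 collapse exponent because the power law requires
physically implausible negative transmural pressures (hundreds of mmHg) to
push a ~100 mm² lumen below 0.5 mm²; the exponential form occludes at
k·ln(a_ref/0.5)/n_neg ≈ 10.6 mmHg below external pressure for the defaults.
The law is strictly increasing, so per-frame inversion is a bracketed
Brent root solve on p_ijv ∈ [−5, 40] mmHg with area tolerance
10⁻³·a_ref ("about equal" areas, quantified).

**Defaults** (plausible round numbers, not fitted patient values): a_ref =
100 mm², k = 2 mmHg, n_pos = 2, n_neg = 1, contact area 15 cm² (a
large-footprint matrix probe), transmission 0.4 (→ 2 mmHg of vessel-level
pressure per newton), κ = 0.02 of the carotid pulse pressure, carotid
a_ref = 50 mm² with 0.25 mm²/mmHg compliance about 70 mmHg. With these,
synthetic collapse forces span ≈ 5.5–10.5 N over mean CVPs of 0.5–10.5 mmHg.

## Waveform reconstruction

`estimate_cvp_waveform` operates on the constant-force hold. Measured areas
are first smoothed with a 0.1 s moving average (segmentation denoising; a
side effect is mild attenuation of the sharpest cardiac components, so
reconstructions are slightly dampened, with the fast a/c morphology least
distinct — and under area noise the recovered amplitude never exceeds the
truth). The tube stiffness k is then calibrated so the reconstruction's
time-mean equals the CF-based mean CVP estimate supplied as the anchor:
because the inverted pressure is affine in k under this law, the
calibration is an exact one-step solve rather than an outer iteration, and
it is a physical-parameter calibration rather than a post-hoc additive
shift, keeping the forward model self-consistent. The anchor is the CF-only
prediction (not CF+HO). Frames whose area is unattainable (occluded or
beyond distension saturation) are flagged, linearly interpolated, and
counted; more than 20% of them is a failure. The carotid input is the
simplified two-level (end-diastole/peak-systole) pulse; its systolic window
covers the venous v wave, so with κ > 0 the inversion correctly credits
part of the v-time area dip to carotid push rather than to low venous
pressure — ignoring the coupling (κ = 0) under-reads the v peak.

## Synthetic data: what it emulates, what it does not

The CVP generator sums a mean level, per-beat Gaussian bumps for a/c/v
(positive) and x/y (negative descents) at fixed intra-beat phases (0.10,
0.25, 0.40, 0.65, 0.85 of the RR interval, widths 5% of the beat), a
respiratory sinusoid, and white Gaussian noise; the cardiac component is
centered so the time-mean equals the specified mean CVP. Defaults: 75 bpm,
12 breaths/min, respiratory amplitude 1 mmHg, noise 0.1 mmHg, 100 Hz,
30 s. The capture protocol ramps at 1.5 N/s to 4 N past nominal occlusion,
holds ~15 s at a lightly compressed area, and inserts 0.4 s half-sine²
sync compressions; ramp rate, hold force and spike shape are this package's
own defaults — the acquisition they emulate names the maneuvers but not the
numbers.

Passing tests on these data show that the estimators are *consistent with
the generating model*: collapse detection matches the generator's recorded
truth, the CF→CVP correlation emerges from the tube mechanics alone
(r² > 0.95 noise-free), the inversion round-trips (RMSE ≈ 3% of waveform
range), and truth-derived intervals achieve overlap accuracy 1.0 that
degrades monotonically as intervals shrink. They do not establish
performance on real ultrasound: no B-mode imaging or segmentation error
model, no tissue mechanics beyond the uniform-transmission approximation,
no beat-to-beat variability, arrhythmia, or probe motion, and a tube law
that is qualitatively, not histologically, vein-like. The published
force-method overlap accuracies (0.778, 0.889) depend on the study's raw
per-subject waveforms and are not reproducible from the summary table;
only the JVP accuracy (0.125) is, and it is asserted exactly.

## Numerical notes and limitations

* Band-split edge effects are controlled by reflection padding; the
  idempotence of the respiratory filter holds away from series edges.
* The fit of invasive CVP on CF and HO from the table's rounded values gives
  multilinear coefficients (≈1.041, ≈0.229 per mmHg of HO, ≈−0.634) that
  differ from the published rounded ones; r² (0.83) and the
  non-significance of HO (p ≈ 0.51) are the stable quantities and the only
  ones asserted.
* Inversion is ill-posed where the pressure–area law is flat (full occlusion
  and distension saturation); such frames are flagged rather than solved.
* The overlap statistic is a coverage count on a small cohort; one subject
  changes a force-method accuracy by 1/9.
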