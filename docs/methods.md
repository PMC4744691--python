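# Methods

## The problem

When xylem sap cavitates under drought tension, the abrupt tension release
emits an ultrasonic click — an acoustic emission (AE). Counting AE during a
controlled dehydration is the classic non-destructive route to a
vulnerability curve, but it has a well-known failure mode: hits keep
arriving long after the sample has lost all hydraulic conductivity
(cavitating fibres, ray cells, shrinkage micro-fractures). Cumulative-count
analyses therefore drift toward overly negative vulnerability estimates
unless the recording is cut off by hand.

`cavitrace` implements the rate-based alternative: instead of asking "what
fraction of total AE has occurred by Ψ?", it asks "when is AE *activity*
(hits·min⁻¹) highest?". If the water potential declines roughly linearly in
time, the activity peak falls where the most conduits cavitate per unit Ψ —
the steepest part of the vulnerability curve, i.e. near its inflection
point P50. The Ψ interpolated at the activity peak is called P_maxrate.
Late-stage signals form a low, drawn-out tail rather than a concentrated
peak, so they do not capture the argmax.

## P_maxrate pipeline

1. **Amplitude filter.** Hits below 45 dB (default, configurable) are
   discarded; this is the conventional detection floor separating
   cavitation-sized events from electronic and handling noise.
2. **Activity.** Hits·min⁻¹ on a 1-min grid, each value the count in a
   centred 15-min window divided by the actual (boundary-truncated) window
   width. Centred windows pair with the symmetric smoother below and avoid
   a systematic lag of the peak time; dividing by the actual width keeps
   boundary estimates unbiased instead of shrunken.
3. **Smoothing.** Savitzky–Golay, polynomial order 5, window 7 grid points
   (the conventional window for a 5th-order filter). SG is chosen because
   it damps counting noise while preserving peak position and height —
   exactly the feature the estimator reads off. Negative smoothed values
   are floored at zero (counted and warned).
4. **Peak.** Global argmax of the smoothed activity; exact ties break to
   the earliest time, because late activity is the artifact regime.
5. **Ψ at the peak.** Linear interpolation between the bracketing
   pressure-chamber readings. No extrapolation: a peak outside the Ψ
   observation span is an error, not a guess. A quality flag records
   whether the interpolated Ψ is within 0.3 MPa of the nearest measured
   reading — runs with sparse Ψ sampling around the peak are flagged, not
   rejected; the user decides.

A warning (not a correction) is issued when the Ψ trace is strongly
nonlinear in time (linear fit R² < 0.85): under decelerating drying the
activity peak reflects events per unit *time*, which no longer maps 1:1
onto events per unit Ψ. No algorithmic correction is applied because none
is established.

## Vulnerability curves

The reference hydraulic method fits the reparameterised Weibull, in which
the parameters are directly Px (Ψ at x% loss of conductivity) and Sx (slope
at Px, % per MPa). With P = |Ψ|:

    relK(P) = (1 − x/100)^((P/Px)^(Px·Sx/V)),  V = (x − 100)·ln(1 − x/100),
    PLC(P)  = 100·(1 − relK(P)).

Two properties make this form convenient and are enforced as invariants:
PLC(Px) = x identically, and dPLC/dP|_{Px} = Sx. Conversion to the classic
(b, c) Weibull is provided and round-trips to 1e-9.

Fitting is unweighted nonlinear least squares on PLC vs Ψ
(`scipy.optimize.curve_fit`, bounded), with data-driven starting values
(Px₀ = Ψ of the point with PLC nearest x; Sx₀ from a local linear fit). Data
that do not bracket the x% level yield a warning — the fitted Px is then an
extrapolation.

Confidence intervals follow the two workflows real datasets impose:

* **Pooled data** (destructive benchtop drying, one curve per species):
  case-resampling bootstrap at the measurement level, percentile 2.5/97.5
  of the replicate Px values; 999 replicates by default. Percentile is the
  minimal-assumption choice; non-converged replicates are dropped and
  counted, with a warning above 10%.
* **Per-sample fits** (centrifuge, 3–5 curves per species): parameters are
  averaged and the CI is the normal approximation mean ± 1.96·SE with
  SE = sd/√n. No CI is reported for n < 3 — an SE from two values is not
  meaningful.

## Cross-method regression

Species-level comparison regresses |P_maxrate| on |P50| (tension
magnitudes) by OLS. Magnitude vs signed fitting changes only the sign of
the intercept (slope and R² are invariant — asserted as a test); the
magnitude-space intercept is what is reported, with the signed equivalent
exposed as `intercept_signed`. On the packaged 18-entry reference panel
(16 species + 3 apple cultivars; 15 angiosperm entries, 3 conifers) this
gives slope 1.20, intercept −0.12, R² 0.76, slope p < 0.001, intercept
p = 0.86 — the acceptance suite checks these to two decimals.

Because n = 18, influence matters: hat-matrix leverages and Cook's
distances are computed per species (verified in tests against perturbation
and leave-one-out refit oracles), and `sensitivity_refit` re-estimates the
line after dropping the most influential point or the species with n < 2
P_maxrate samples. On the reference panel all such refits move the slope
and R² by < 0.1.

## Synthetic dehydration experiments

The simulator exists so that every stage has ground truth. Its components:

* **Cavitation AE.** Each of `n_conduits` conduits draws a threshold Ψᵢ
  from the distribution whose CDF is the true vulnerability curve
  (inverse-CDF sampling; Kolmogorov–Smirnov distance to the target CDF
  < 0.02 at n = 10⁵, tested), and emits exactly one hit when Ψ(t) first
  reaches Ψᵢ. One-hit-per-conduit reflects the physical picture that a
  cavitation event, in a wide vessel or a narrow tracheid alike, produces
  one emission; what the simulator deliberately omits is the *hydraulic
  weighting* of those events — which is precisely why P_maxrate tracks the
  threshold-density mode rather than P50 itself.
* **Late-stage noise.** An inhomogeneous Poisson process with intensity
  `noise_rate_max · logistic((noise_onset − Ψ(t)) / noise_width)`,
  simulated by thinning. This is an empirical onset model, not a
  mechanistic one; defaults (2 hits·min⁻¹ plateau, onset −6 MPa, width
  0.5 MPa) place the noise where cavitation is essentially complete for
  the default curve.
* **Trajectory.** Ψ(t) = Ψ_min + (Ψ₀ − Ψ_min)·e^(−t/τ) by default
  (benchtop drying decelerates; defaults −0.5 → −9 MPa, τ = 10 h ≈ a
  two-day dry-down), or piecewise-linear knots for constant-rate analytic
  checks. The desk-scale constant-rate condition used in the recovery
  tests is −0.5 → −9.0 MPa over 850 min (≈ 0.01 MPa·min⁻¹).
* **Amplitudes.** Normal(60, 10) dB truncated to [35, 99]; they exist only
  to exercise the amplitude filter — the analysis is amplitude-blind above
  threshold.
* **Ψ readings.** Every 30 min with 0.05 MPa Gaussian reading error.

The truth record stores the analytic mode of the threshold density
(closed form: with c = Px·Sx/V and L0 = ln(1 − x/100), the mode is
Px·((c−1)/(−L0·c))^(1/c) for c > 1) and, for non-constant drying, the
argmax of the cavitation hit intensity f(Ψ(t))·|dΨ/dt| along the
trajectory.

**What the simulator does not emulate:** acoustic propagation and
attenuation, sensor coupling variability, temperature effects, re-emission
from a single conduit, and hydraulic conductance weighting of events. A
passing recovery test therefore shows the *estimator chain* is correct
given the generative assumptions, not that P_maxrate equals P50 in real
wood — on real material the two differ systematically (more negative
P_maxrate in most angiosperms, less negative in conifers).

## Numerical choices and degenerate inputs

* Windows are closed intervals; a hit exactly on a window edge (measure
  zero for real logs) counts in both adjacent windows.
* Peak ties break to the earliest grid time.
* The estimator's sampling jitter at 5000 events is appreciable (sd
  ≈ 0.2 MPa for the default broad curve) because the Weibull threshold
  density is flat near its mode; recovery guarantees are therefore stated
  and tested as seed-ensemble means, and single runs should be read with
  the QC flag and the rate series, not as point truth.
* PLC outside [0, 100] from noisy flow ratios is clipped with a warning.
* Empty hit streams: a recording with a declared duration and no hits has
  zero activity everywhere; the all-zero series is refused at peak
  detection ("no acoustic activity"), and an amplitude filter that removes
  every hit is refused at the pipeline entrance.
* Bootstrap and simulator randomness flows through a single
  `numpy.random.default_rng` seed; identical seeds give bit-identical
  outputs.

## Problem sizes

Desk-scale defaults keep the full validation chain fast: 20-seed recovery
ensembles at 5000 cavitation events each, and bootstrap coverage over 200
simulated datasets at 199 replicates (the production default for a single
dataset remains 999). These sizes give a coverage standard error of ≈ 1.8
percentage points and a recovery-mean standard error of ≈ 0.05 MPa.

## Known limitations

* P_maxrate estimates the threshold-density mode, which coincides with P50
  only when AE events map 1:1 onto conductivity loss; the package reports
  the regression between methods rather than pretending identity.
* No correction for non-constant drying rates is implemented (warning
  only).
* The late-stage noise model is phenomenological; its parameters are
  configuration, not claims about fibre or ray acoustics.
* Energy-weighted activity and amplitude clustering are out of scope.
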