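# Methods

`liverkin` estimates liver FDG kinetics from short dynamic PET
time-activity curves (TACs).  This note records the models, the
numerical choices, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the design was genuinely
open.

## The kinetic model

The liver receives arterial and portal-venous blood.  The model input
is the perfusion-weighted mixture

    C_B(t) = HPI * A(t) + (1 - HPI) * V(t)

with A and V the abdominal-aorta and portal-vein concentration curves
and HPI (hepatic perfusion index) the arterial fraction of the total
supply.  Tracer exchanges between blood and a free tissue pool (K1,
mL/min/mL in; k2, 1/min out) and between the free and phosphorylated
pools (k3, k4, 1/min):

    dC_E/dt = K1 C_B - (k2 + k3) C_E + k4 C_M
    dC_M/dt = k3 C_E - k4 C_M
    C_T(t)  = (1 - Vb) (C_E + C_M) + Vb C_B(t)

where Vb is the fractional blood volume of the region.  The solution is
the bi-exponential convolution

    C_T = (1 - Vb) * h (*) C_B + Vb * C_B
    h(t) = K1/(T2-T1) [(k3+k4-T1) e^(-T1 t) + (T2-k3-k4) e^(-T2 t)]

with macro rates T1 <= T2 the roots of
`lambda^2 - (k2+k3+k4) lambda + k2 k4`.  Repeated roots and the k4 = 0
irreversible limit are handled by their analytic limits rather than by
epsilon-jitter, which keeps the optimiser's objective free of
tolerance-dependent branches.

A note on units: published tables in this literature sometimes print
k2-k4 as "1/mL"; that is dimensionally inconsistent for first-order
rate constants and `liverkin` uses 1/min throughout, as in the
standard kinetic literature.

## Acquisition protocols

Two frame schedules are built in:

* `short_term` — 12 x 5 s + 4 x 60 s dynamic frames (0-300 s) plus one
  1-min static frame at 60 min post-injection (17 frames).  The static
  point is placed at [3600 s, 3660 s]; the convention for attaching it
  is not standardised, and one 1-min bed position is the natural
  reading.
* `full_dynamic` — 12 x 5 s, 9 x 60 s, 10 x 120 s, 6 x 300 s
  (37 frames, 0-3600 s).

Both share the first 16 frames, so a full dynamic acquisition can be
read out as a short-term one.

Frame values are treated as time-averages of the underlying
concentration over the frame (PET reconstruction physics), not
instantaneous samples; `frame_average` integrates by trapezoid rule at
a <= 0.1 s step, and `continuous_from_frames` inverts this
approximately by midpoint-anchored linear interpolation with constant
edge extrapolation.

## Fitting

Both estimators minimise the weighted residual sum of squares

    WRSS(theta) = sum_i w_i (c_i - C_T(t_i; theta))^2

over frame-averaged predictions (the sum-of-squares form; a published
variant of this objective omits the square on the residual, which has
no minimising interpretation and is read as an erratum).

* Three-compartment model: theta = [K1, k2, k3, k4, HPI, Vb], bounds
  K1, k2 in [0, 10], k3, k4 in [0, 1], HPI, Vb in [0, 1].
* Combined model: HPI is measured first by the maximum-slope method
  and held fixed; theta = [K1, k2, k3, k4, Vb].

The optimiser is bounded trust-region least squares
(`scipy.optimize.least_squares`, TRF) restarted from a fixed
physiological start (K1=1, k2=1, k3=0.01, k4=0.01, HPI=0.5, Vb=0.05)
plus seeded scrambled-Sobol draws over the bounds (default 10 starts);
the 6-parameter landscape is multi-modal and the best-of-starts WRSS
is reported.  Convergence tolerances are 1e-10 (ftol/xtol) with at
most 500 function evaluations per start.

**Weights.** The default is *uniform* weights.  With SUV-scaled TACs
the measurement noise grows with the signal, so weighting by frame
duration (a natural choice when noise is count-limited and
signal-independent) concentrates the objective on the late, high-value
frames and leaves the twelve 5-s first-pass frames — the only data
that identify HPI and Vb — with about 1/12 of the influence.  In
simulation this destroys the short-vs-full protocol agreement of HPI
and Vb (Pearson r drops from ~0.97 to ~0.1 at 5% frame noise) while
uniform weights preserve it.  A `duration` mode is retained.

**Forward-model numerics.** The convolution is evaluated on a uniform
0.5 s grid by FFT with a trapezoid end-point correction, then
frame-averaged; rates are converted to per-minute at this boundary.
Against direct ODE integration of the two-tissue system the curves
agree to better than 0.1% of the curve maximum over the full
short-term grid (this is an acceptance test).  The 6-parameter model
has an extremely flat HPI-Vb trade-off valley — curve differences of
order 0.1% of the signal span parameter excursions of order one — so
recovery experiments must use a consistent forward model between
simulation and fit; the forward model itself is validated against the
independent ODE oracle, not against itself.

**Input functions.** Fits take continuous A(t), V(t).  The pipeline
derives them from the measured aorta and portal-vein TACs
(image-derived input functions) by midpoint-linear interpolation; no
population input function is used.  Because both protocols read the
same frames, short-term and full-protocol fits share their input
curves exactly, as a clinical re-binning would.  An optional smoothing
mode (`smoothed_input_from_frames`) gamma-variate-fits each vessel's
first pass and cross-fades over 10 s into the interpolated tail; it
suppresses first-pass vessel noise but decouples the input from the
measured frames, and in simulation it trades portal/arterial-fraction
agreement for washout-rate agreement, so raw interpolation stays the
default.

**Goodness of fit** is R = 1 - sqrt(sum (y-yhat)^2 / sum y^2), 1 for a
perfect fit, 0 for a fit no better than zero; conventionally reported
x100.

## Maximum-slope perfusion

First-pass bolus curves are fitted with the gamma variate

    Y(t) = y_max ((t-t0)/t_max)^alpha exp(alpha (1 - (t-t0)/t_max))

(zero for t <= t0).  The arrival offset t0 extends the classical form,
which is recovered at t0 = 0.  The default fit window runs from the
first frame to the first local minimum after the global peak, which
excludes the recirculation rise; fits are least squares at frame
midpoints, multi-started over alpha in {1, 2, 4, 8}.

The splenic parenchymal peak time (from the spleen gamma fit) splits
the tissue curve into an arterial and a portal-venous phase.  Phase
slopes come from gamma refits on the phase windows; these refits carry
a constant baseline (the activity already present at the phase onset)
and an alpha >= 1 bound, because a zero-onset gamma cannot represent a
non-zero starting level except through a sub-unity alpha whose onset
slope is unbounded.  Then

    HAP = S_ART / A_ART * 6000     HVP = S_PV / A_PV * 6000
    TLP = HAP + HVP                HPI = HAP / TLP

with S the phase-restricted maximum upslopes (activity/s), A_ART and
A_PV the fitted aortic and portal peak values, and 6000 the
mL/mL/s -> mL/100 mL/min conversion.  For alpha > 1 the maximum
upslope is analytic (maximiser at t0 + t_max (1 - 1/sqrt(alpha)));
alpha <= 1 falls back to a 0.1 s finite-difference grid and is flagged
as a degenerate onset.  Time to peak is TTP = ROI fitted peak time
minus aortic fitted peak time; negative values are allowed.

**Known bias.** Under the full kinetic simulation the maximum-slope
HPI is biased toward 0.5 relative to the generating HPI: after the
splenic peak the tissue slope still contains arterially-driven FDG
uptake, which the method attributes to portal inflow (its no-outflow,
pure-perfusion premise does not hold for a trapped tracer).  The
estimate is, however, several-fold more precise than the fitted
6-parameter HPI — which is exactly why fixing it inside the
compartment fit (the combined model) stabilises the remaining
parameters.

## Synthetic data

The generator emulates the study design at desk scale; its defaults
are the study conditions.

* Arterial input: zero until an 8 s delay, linear rise over 22 s to a
  peak of 35.2 activity units (aortic peak near 30 s), then
  tri-exponential washout with amplitudes (28, 6, 1.2) and rates
  (3.0, 0.4, 0.012) 1/min.
* Portal input: the arterial curve convolved with a mass-preserving
  25 s exponential dispersion kernel (splanchnic transit); portal peak
  is later and lower than the aortic peak.
* Spleen: a high-flow one-compartment tissue (K1 = 1.0 mL/min/mL,
  k2 = 1.2/min, Vb = 0.3) fed by the artery; it exists to mark the
  arterial-to-portal transition for the maximum-slope method.
* Tissue truths: truncated normal draws per group.  The default group
  distributions are the published combined-model summaries for HCC
  (HPI 0.764 +/- 0.121, K1 1.52 +/- 0.61, k2 1.84 +/- 0.56,
  k3 0.046 +/- 0.047, k4 0.021 +/- 0.027, Vb 0.052 +/- 0.053) and
  background liver (HPI 0.428 +/- 0.171, K1 1.00 +/- 0.63,
  k2 1.01 +/- 0.59, k3 0.005 +/- 0.007, k4 0.023 +/- 0.034,
  Vb 0.003 +/- 0.007); the six-parameter-model summaries are
  selectable.  Truncation keeps rates positive (1e-3 floor for k3,
  k4, Vb, 0.05 for K1, k2) so that relative recovery errors are
  well-defined, and fractions inside (0, 1).
* Noise: Gaussian per frame with SD = noise_cv * value /
  sqrt(duration/5 s) — 5-s frames carry the nominal CV, longer frames
  are quieter as counts average — clipped at zero.  The two protocols
  are read out from one simulated session, so they share the noisy
  first 16 frames exactly as a clinical re-binning would; the static
  frame has its own noise draw.

What the generator does **not** emulate: attenuation/scatter physics
and reconstruction correlations between frames, partial-volume and
spillover between vessel and tissue ROIs, tracer-arrival delay and
dispersion differences between the aortic ROI and the liver inlet,
patient motion, and SUVmax-specific (max-of-ROI) noise statistics.
Passing tests therefore demonstrate estimator correctness and the
internal consistency of the pipeline under a plausible noise model,
not clinical performance.

## Problem sizes used by the test suite and acceptance script

Forward-model validation uses 100 random parameter draws (10 in the
unit test); macro-rate algebra 10,000; noiseless combined-model
recovery 100 subjects (50 per group) with 3 optimiser starts, which
suffices because noiseless objectives are convex near truth; protocol
equivalence 27 subjects (14 HCC + 13 liver) at noise_cv = 0.05;
precision comparison 50 replicates of the HCC-mean subject.  The
acceptance script re-runs the same computations at reduced sizes
(20 forward-model draws, 30 recovery subjects, 16 protocol subjects,
20 replicates) chosen as the smallest cohorts whose Monte-Carlo error
leaves the qualitative conclusions stable.

## Known limitations

* k4 is weakly identified at realistic noise; its protocol-agreement
  correlation is the weakest of the six parameters (the published
  study reports the same) and recovery tolerances do not bind it.
* At 5% first-pass frame noise the six-parameter k2 is not reliably
  transferable between protocols in this simulation: for roughly one
  subject in seven the noisy objective's global minimum displaces k2
  toward a bound with compensating HPI/Vb shifts (verified by
  comparing the displaced optimum's WRSS against a truth-started
  fit), capping the simulated short-vs-full k2 correlation near 0.8
  where K1, HPI and Vb reach 0.94-0.98.  Published real-data k2
  agreement is higher, implying a noise structure more favourable
  than this generator's.
* The 6-parameter model's HPI-Vb valley makes single-subject
  6-parameter fits unstable at 5% frame noise; conclusions about
  individual subjects should use the combined model.
* No delay/dispersion correction between vessel ROIs and the tissue
  inlet; no partial-volume or spillover model (out of scope).
* Passing-Bablok confidence intervals use the original rank-based
  normal approximation, not bootstrap; ROC p-values use the
  normal-approximated Mann-Whitney test, not DeLong.
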