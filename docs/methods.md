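# Methods

This note documents the statistical model behind `spikelight`, the design
choices made where the design was genuinely open, and what the synthetic
validation suite does and does not establish about real recordings.

## Baseline spiking model

Each unit's spontaneous activity is a gamma-renewal process: interspike
intervals are i.i.d. Gamma(k, θ) with shape k = 1/CV² and mean kθ = 1/rate.
This gives independent control of the two axes the striatal classifier
uses (firing rate and ISI CV): Poisson firing is the k = 1 special case,
regular tonic firing (TANs, CV ≈ 0.5) uses k = 4, and burstier-than-Poisson
units (PANs, CV ≈ 1.5) use k < 1. Default baseline phenotypes
(`BASELINE_PROFILES`): PAN 1 spikes/s CV 1.5, TAN 5/0.5, FSN 20/0.8,
GPe 60/0.8, VL 15/1.2.

The renewal process is *ordinary* (started at a renewal epoch), so empirical
rates carry an O(1/duration) bias; at the 120 s minimum baseline this is
negligible relative to sampling noise.

## Channel gating

ChR2 opening is modeled as a two-state first-order system: during light
do/dt = (1 − o)/τ_on, after light do/dt = −o/τ_off, evaluated piecewise in
closed form. Defaults τ_on = 1 ms, τ_off = 20 ms (the H134R variant). A
0.1 ms pulse reaches o ≈ 0.095 while a 20 ms pulse saturates (o ≈ 1), which
is what makes very short pulses ineffective and everything from ~0.6 ms up
effective in the dose–response analyses. The model deliberately omits
desensitization, photon transport, and membrane biophysics: it is a
phenomenological drive, not a conductance model.

## Light-evoked rate modulation

The conditional intensity of a responsive unit is

λ(t) = r · g^( s · o(t − ℓ) · d(p(t)) · L(I) ),

where r is the baseline rate, g the gain (rate factor at full sustained
activation), s = +1 for excitation and −1 for inhibition, ℓ a pure latency
shift, d(p) = f^(p−1) a per-pulse drive decrement for pulse index p within a
train, and L(I) = 1 / (1 + (I₅₀/I)^h) a logistic function of log light
intensity (default half-max I₅₀ = 8 mW/mm², slope h = 2). Modulation is
multiplicative in the exponent so inhibition can never drive the rate
negative, and L → 0 recovers the baseline process exactly (scaling the
*drive* rather than the gain itself; a gain scaled to zero would silence the
unit instead of de-sensitizing it). COMBINATION responders additionally
multiply the rate by (1 − suppression_depth) for suppression_duration after
the end of each train.

**Transient responders.** A sustained drive makes λ rise monotonically
through a 20 ms pulse, so the peak PSTH bin falls anywhere in the saturated
second half of the pulse. Rapidly responding thalamic units instead fire a
time-locked burst within a few ms of pulse onset. An optional per-pulse
adaptation term exp(−Δt/τ_adapt) multiplying the drive (off by default)
produces this phenotype; the `vl_transient` fixture uses τ_adapt = 5 ms with
a large nominal gain (1000), giving peak instantaneous rates of a few
hundred Hz for a few ms — about one well-timed spike per pulse — while the
nominal sustained factor is never realized. Striatal-type responders leave
adaptation off and peak late in the pulse.

**Drive vs spike-count decrement.** Because d(p) attenuates the exponent,
the gain amplifies it: f = 0.8 yields a ~6.5× first-vs-rest evoked-count
ratio, while f = 0.98 yields the ~1.2–1.3× ratio typical of decrementing
responders. The validation suite uses the strong setting where a
well-conditioned machinery check matters and the mild setting where the
phenotype itself is reported.

## Exact sampling by time rescaling

The modulated process is sampled by generating the baseline gamma-renewal
train in operational time and mapping spike times through the inverse of
Λ(t) = ∫₀ᵗ m(u) du, with m = λ/r the modulation factor. Λ is accumulated
from per-train templates on a 0.05 ms grid (trapezoid rule) and inverted by
linear interpolation; trains with identical parameters share one template.
Thinning was considered and rejected: thinning a homogeneous Poisson
envelope yields a Poisson process (breaking the requirement that a gain-1
session equal the gamma baseline in distribution), and the gamma hazard is
unbounded near zero for CV > 1, which rules out conditional-intensity
thinning for the bursty phenotypes. With gain = 1 the rescaling map is the
identity, so unresponsive units are *exactly* the baseline process — the
rate-conservation tests check this both bitwise and by KS on ISIs.

Output timestamps are quantized to 10 µs (the stimulus-timing precision and
the serialization resolution); colliding spikes (never observed at
physiological rates) would be merged.

## Detector

The 2-SD run criterion operates on the trial-summed PSTH: μ and σ are the
mean and **sample** SD (ddof = 1; the convention is not externally fixed)
of the 40 baseline bin counts, and runs of ≥2 consecutive post-onset bins
strictly above μ + 2σ / below μ − 2σ give increase/decrease evidence.
Categories: COMBINATION requires an increase run ending before a decrease
run begins; otherwise INCREASE takes precedence over DECREASE when both
are present (a tie that essentially never occurs in practice). With σ = 0
(silent or perfectly regular baselines) the strict inequality makes the
rule permissive; such results carry a `sigma_zero` flag. Results from fewer
than 30 trials are flagged `provisional`.

**Null calibration.** The criterion's false-positive rate on homogeneous
Poisson baselines (50 trials, 8.125 ms bins, 40+40 windows) is
rate-dependent through count discreteness: ≈7–8% for tonic rates
(20–60 spikes/s), ≈9% at 5 spikes/s, and ≈13% at 1 spikes/s, where baseline
bins hold mostly zeros and the threshold collapses to ~2 spikes. The
calibration suite asserts the band [2%, 10%] for the tonic Poisson
reference and stability (±3 pp) across 5–60 spikes/s; the low-rate
deviation is a property of the published criterion, not of this
implementation, and is why near-silent units should be interpreted with
the magnitude statistic alongside the category label.

**Composite category in the pipeline.** The standard 40-bin stimulation
window ends 5 ms after a 320 ms train, so suppression that begins at train
end is invisible to the windowed detector. `analyze_unit` therefore also
scans an extended PSTH (96 post bins = 780 ms) with the post-train
suppression rule and upgrades INCREASE to COMBINATION when suppression is
found — one consistent reading of "increase followed by decrease".
Suppression duration is the run length from the first sub-threshold bin
after train end to the first bin back at or above threshold; an
alternative (first return of the *rate* to baseline) would give slightly
longer durations.

## Magnitude, latency, normalization

Fold-change uses equal-duration windows with a 1-spike floor in the
denominator so silent baselines give large finite ratios (flagged
`zero_baseline`) rather than infinities. Latency is reported at bin
centers with ties to the earliest bin, from PSTHs aligned to the first
pulse of each train only (later pulses can decrement). Population traces
divide each unit's PSTH by its own maximal bin before averaging, so units
with very different absolute rates contribute equal shapes.

## Dose–response

Pulse-width magnitude uses half-open windows (onset, onset+20 ms] and
(onset−20 ms, onset] — edge handling is a convention, chosen half-open so
a spike exactly at onset counts as evoked. Significance per width and per
intensity block reuses the train-level 2-SD detector on pulse-aligned
1 ms-bin PSTHs rather than introducing a second test. Intensity blocks are
maximal runs of consecutive same-irradiance trains, so a revisited
intensity forms its own block. Per-pulse evoked counts in the decrement
analysis are baseline-corrected (rate × window) to make ratios comparable
across units; no parametric dose–response curve is fitted.

## Cohort statistics

Percentages are rounded half-up to one decimal. Striatal class rows count
only QC-passed single units; region rows count every analyzed unit. The
Mann-Whitney comparison enumerates all label permutations exactly (with
midrank ties) for combined n ≤ 20 — two-sided p as the probability of a
min(U_a, U_b) at least as extreme — and uses scipy's tie-corrected normal
approximation above that. The exact branch is checked against an
independent pairwise-comparison enumeration oracle.

## Validation scale and scope

Recovery suites use 200 replicates per condition at the protocol scale of
the experiments they emulate (50 trains of 10 × 20 ms pulses at 30 Hz;
50 trials per pulse-width or intensity condition; 600 s baselines for
classification), sizes at which every suite completes in seconds. What
passing shows: the implementation of each rule is correct (oracle
equivalence, exact arithmetic on constructed inputs) and the pipeline
recovers known ground truth under the generator's assumptions. What it
does not show: robustness to spike-sorting errors, electrical artifacts,
non-stationary baselines, or network dynamics beyond the phenomenological
inhibition/suppression terms — none of which the generator emulates.

## Known limitations

* The generator's inhibition and combination responses are phenomenological
  (no mechanistic model of local GABAergic circuits).
* The two-state channel model omits desensitization; within-pulse response
  decay is modeled by the separate adaptation term.
* The run-based suppression duration underestimates slightly when a single
  noisy bin interrupts a long suppression epoch (the run ends at the first
  recovered bin).
* Low-rate (<2 spikes/s) baselines inflate the detector's false-positive
  rate; see Null calibration.
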