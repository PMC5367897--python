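# Methods

This note documents the models, the synthetic-stimulus conventions, the
numerical choices, and the design decisions taken where the published
description of this paradigm leaves the implementation open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The stimulus: tone-cloud textures with a statistical change

A trial is a train of 30 ms chords. Each chord holds a Poisson number of
pure tones (mean 2 tones/octave × 2.2 octaves = 4.4 tones/chord, ≈147
tones/s). A tone is placed by drawing one of eight spectral bins from the
trial's *marginal distribution* and then one of the bin's 3–4 semitone-spaced
frequencies (26 tones from 400 Hz; the inclusive semitone enumeration over
2.2 octaves yields 27, and the grid drops the top tone by default — both
conventions are selectable). Bins are contiguous groups of tones
(4/3/3/3/4/3/3/3 from low to high), each spanning 3.3 semitones of the log
axis, so adjacent-bin ("localized") changes span 0.55 octave and the tested
non-adjacent distances D = 2, 3, 5, 7 bins correspond to 6.6, 9.9, 16.5 and
23.1 semitones.

The baseline marginal assigns the levels {0.083 ×3, 0.125 ×2, 0.188 ×3} to
the bins in random order. These printed values sum to 1.063; we treat them
as rounded and renormalize after assignment, so every marginal sums to 1
exactly. At the change time two bins are incremented by
`size/100 × 1/8` each (e.g. 0.0625 at 50%) and the vector renormalized:
the expected tone rate — and hence the level — is identical before and after
the change, removing loudness cues by construction.

Change times are exponential (mean 3.2 s) restricted to [0, 8] s by
*redraw*, not clipping: clipping would pile mass at 8 s, whereas redrawing
keeps the density exponential on the whole interval (constant probability of
a change per unit time — the property that defeats timing strategies). The
response window is 2 s; presentation level roves uniformly over 60–80 dB per
trial (relative full scale; absolute SPL calibration is out of scope).
Rendered audio uses 30 ms gated sinusoids with 5 ms raised-cosine ramps;
trials default to 16 kHz sampling in analyses (the tones top out at 1.8 kHz)
with 100 kHz available.

All randomness flows through seeded generators; a top-level seed expands to
per-trial seeds through a counter scheme, so any subset of a batch is
reproducible in isolation. The default batch reproduces the behavioral
design: 4 sizes × 4 localized pairs × 30 repetitions plus the 110% change
over all 15 non-adjacent pairs × 30 = 930 trials.

## Behavioral statistics

A press at or before the change is a false alarm; within 2 s after it, a
hit; anything else a miss. Performance is hits/(hits+misses). Change times
are binned at the quantiles of the capped exponential law (exponentially
widening bins with equal expected counts); the 4-bin equal-count variant
used for electrophysiological averaging is also provided.

*Time-resolved d′* is `Z(HR(t)) − Z(FAR(t))`. HR(t) comes from trials
changing near t; FAR(t) from 2 s no-change windows starting at t (windows
advance with the 0.25 s analysis grid and therefore overlap), each window
counting a press as an artificial false-alarm reaction time. Rates are
clipped to [1/(2N), 1−1/(2N)] before the inverse normal, and cells with
fewer than 50 trials are reported missing rather than fed through Z — rates
estimated from a handful of trials produce wild sensitivity values. The
grid average `mean_dprime` pools by inverse delta-method variance by
default. The analysis is validated on a memoryless surrogate responder
(binomial p = 0.01 per 25 ms bin), for which d′ ≈ 0 at every time.

*Performance dynamics* are fitted with an Erlang CDF,
`P(t_c) = P0 + Pmax · γ(k, t_c/τ)/(k−1)!` (the regularized incomplete
gamma), by nonlinear least squares with bounds τ > 0, P0 ≥ 0, P0 + Pmax ≤ 1
(soft penalty). The integer shape k is shared across change sizes and chosen
by global least squares over k = 1…6; k and τ trade off at behavioral noise
levels, so parameter-recovery statements are made in curve space (or between
extreme sizes), not per-parameter.

*Reaction-time ROC*: hit and false-alarm (pseudo-)reaction-time
distributions are read off at 0.2–2 s in 0.2 s steps; the curve is closed at
(0,0)/(1,1) and integrated by trapezoid. On small samples with a fine grid
this equals the exhaustive pairwise Mann–Whitney comparison exactly.

## Dual-timescale estimation model

Four independent modules, one per pair of bins whose probability can change,
each track their channel input S_i(t) with two leaky estimators:

    dPfast/dt = (S_i − Pfast)/τ_f
    dPslow/dt = (S_i − Pslow)/θ(t),   θ(t) = τ_s − (τ_s − τ_f) e^(−t/τ_a)

A change is detected at the first time |Pfast − Pslow| > T in any channel;
the response follows after Tm = 250 ms. Defaults are the published fit:
τ_f = 0.2 s, τ_s = 1.1 s, τ_a = 0.65 s, T = 0.40, integrated by forward
Euler at dt = 10 ms (an exact exponential update is provided; trajectories
agree within a few percent, and closed-form checks at 1% use the slow time
constant where Euler is that accurate).

Two conventions required a decision because the published equations, read
literally, are unstable (their right-hand sides grow away from the input)
and θ as printed is negative with no asymptote; the implemented forms above
are the ones every verbal description of the model implies (estimators relax
*toward* the input; θ rises from τ_f to τ_s so both processes start on the
same timescale).

**Channel input.** The input is the per-bin tone occupancy of the channel's
two bins (count/2 per chord, held across the chord at 100 Hz). At the
design's tone rates this approximates the per-bin presence probability while
remaining unbounded above — the estimators can transiently exceed 1, and,
decisively, the published threshold T = 0.40 then operates inside the
statistic's dynamic range. With strictly binary presence inputs the
estimator difference never reaches 0.40 and the model would detect nothing;
the binary series remains available (`input_mode="presence"`), with the
threshold then needing to sit near 0.3.

**Initial state.** Estimators start at the stationary occupancy of the
average texture (4.4 tones/chord ÷ 8 bins = 0.55), i.e. the trained
listener's prior, rather than at zero. Zero initialization makes the onset
transient itself cross threshold, which inverts the performance-vs-change-
time dependence and produces a decaying false-alarm hazard; with the prior
the model shows the intended pattern — performance rising with change time
and size, an initial false-alarm hesitation followed by a flat hazard, and
median reaction times decreasing with change size. Zero initialization
remains configurable.

Fitting is an exhaustive grid search (no local minima, no starting-value
bias) minimizing the mean squared error pooled over the performance,
false-alarm and miss curves per (size × change-time bin); the stimulus set
is realized once and reused at every grid point (common random numbers), and
a minimum on a grid edge is flagged. Self-consistency runs (targets
generated by the model itself) recover the generating point exactly.

## Cortical modulation-filterbank model

The cochleogram stage is a 128-channel constant-Q Butterworth filterbank
log-spaced over 5.3 octaves (from 180 Hz at 16 kHz audio), envelope
extraction, 4 ms leaky integration, power-law compression (exponent 0.6),
and spectral sharpening by a half-wave-rectified first difference across
channels (lateral inhibition), framed at 100 Hz. All architecture keys
(channels, span, bandwidth, compression, lateral inhibition) are parameters;
this is a simplified stand-alone cochleogram, not a port of any particular
toolbox. Because the change conserves the total tone rate, each trial's
mean cochleogram energy estimates its roved level, and a divisive gain
normalization to unit mean precedes the modulation stage — without it the
20 dB rove dominates single-trial variance and no fixed decision threshold
is meaningful.

The modulation stage convolves the cochleogram with a separable
spectrotemporal filter: causal temporal kernel `t² e^(−3.5ωt) cos(2πωt)`
(Q ≈ 1) at rate ω, zero-phase spectral Gabor at scale Ω with Gaussian
envelope σ = 0.275/Ω octaves. The σ convention is pinned by the statement
that the Ω = 0.54 cyc/oct kernel has a full width at half maximum of
≈0.56 octave — the spectral span of a localized change; FWHM therefore
scales as ≈0.302/Ω. Averaging the upward and downward drifting quadrants of
a zero-phase separable filter equals the product of its real kernels, which
is what is computed. The filter magnitude is collapsed across the tonotopic
axis to one decision trace (quadratic mean by default; plain mean and a
band restriction are options).

The decision stage normalizes the trace to baseline-plateau units (pooled
pre-change windows), smooths single trials with a matched template — the
trial-averaged change-aligned response, length 1/(2ω) s ≈ 0.69 s at the
default rate — and takes the first local maximum exceeding the collapsing
threshold `T(t) = b e^(−t/λ) + a`, plus the 250 ms motor delay. The
initially elevated bound implements the instruction not to report the
(salient) stimulus onset and delays responses to early changes. Defaults:
ω = 0.72 Hz, Ω = 0.54 cyc/oct, λ = 1.14 s as published; a = 1.10 and
b = 2.0 are in plateau units, calibrated once so the stage operates with
suppressed early false alarms and size-ordered hit rates (the units of the
published a = 6.2, b = 10.8 are tied to an unknown output scaling and are
not comparable).

**Sensitivity of the frequency-averaged readout.** The change drives the
~13 channels around the incremented bins strongly (per-channel response
increases by 50–90% of the plateau at 140%), but collapsing 128 channels
into one trace dilutes this several-fold: single-trial discriminability of
even the largest change is modest (window-max AUC ≈ 0.6–0.7), far below
what a channel-selective readout could achieve. Trial-averaged responses
are nonetheless clear (the 140% late-change peak exceeds the plateau by
many standard errors at ~100 trials/curve), so the model's figure-level
signatures hold: a change-locked peak whose build-up slope grows with
change size, fusion of that peak with the onset response for early changes,
and — in the unselective, EEG-like *signed* sum over the whole filter grid
and all channels, lowpassed at 10 Hz — an onset response with no
change-locked peak. Change-locked average curves fix the baseline marginal
across trials so that across-trial variability is the random tone cloud
alone.

The five-parameter fit (Ω, ω, λ, a, b) minimizes squared error of the
performance and false-alarm curves only; reaction times are produced but
never enter the objective. Cochleograms are computed once per trial set and
reused across the filter grid.

## What the synthetic data do and do not show

The generator *is* the paradigm's stimulus: its statistics (marginals,
Poisson chords, change law, level rove) are fully specified, so model-side
claims (monotonicity, hazard shapes, recovery of generating parameters) are
exact statements about this stimulus family. What it cannot provide is the
human data: performance levels, reaction-time distributions and
EEG statistics of real listeners are not reproducible here, so model-to-
human fit quality is out of scope; the fitting machinery is instead
validated by self-consistency. Passing tests show the pipeline implements
the intended computations on the intended stimulus — not that the models
describe any particular listener.

## Numerical and degenerate-input conventions

- Integration step 10 ms everywhere (models run at 100 Hz); chord-constant
  inputs (3 samples per chord). `dt ≥ τ_f` is rejected as unstable.
- Detection scans padded trial arrays with per-trial validity masks;
  responses after a trial's end are discarded as misses.
- Empty risk sets and undersupported d′ cells are reported missing (NaN),
  never zero.
- Degenerate ROC curves (too few distinct false-alarm probabilities) and
  zero-energy matched templates raise errors rather than returning numbers.
- The matched post-filter edge-pads traces so the template running off the
  ends cannot fabricate peaks; its output is rescaled to preserve constants
  (plateau units survive the filtering).
- Peak detection uses a 3-sample neighborhood with ties broken earliest.
- Waveforms near full scale trigger a clipping warning; per-tone amplitude
  at the loudest rove is 20 dB below full scale.

## Known limitations

- The cortical decision stage's quantitative hit rates are below the
  published model's (see above); qualitative orderings are the supported
  claims.
- The summed EEG-like readout shows a small sustained level shift after the
  change (the lateral-inhibition stage is sensitive to spectral shape), on
  top of which no change-locked peak occurs; "no average change response"
  refers to locked transients.
- Erlang k and τ trade off at realistic noise; per-parameter recovery
  claims are restricted to large samples or extreme-size comparisons.
- The dual model's input convention (per-bin counts) is an interpretation
  forced by the published parameter values; the binary-presence variant is
  retained for comparison.
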