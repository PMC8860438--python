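# Methods

`sospindle` implements an individualized analysis of the temporal
coordination between NREM slow oscillations (SO, < 2 Hz) and sleep
spindles (10–17 Hz), the statistics used to relate that coordination to
gross-motor learning, and a ground-truth simulator that makes every stage
of the chain verifiable by parameter recovery.  This note records the
models, the defaults and their rationale, the numerical choices, and what
the synthetic verification does and does not establish about real data.

## Analysis model

**Spectral individualization.** EEG channels are z-normalized in the time
domain, then averaged power spectra are computed with 15-s Hanning
windows slid in 1-s steps across continuous runs of the requested sleep
stages (default NREM2+NREM3); windows never straddle a stage boundary and
are averaged with equal weight.  The aperiodic ("fractal", 1/f) component
is estimated by irregular resampling: the signal is stretched and
compressed by pairwise factors h = 1.10, 1.15, …, 1.90 (polyphase
rational resampling; the 0.05 steps are exact rationals), the spectra of
each h-pair are geometrically averaged, and the median across factors is
taken.  Resampling displaces any oscillatory peak by h in opposite
directions while leaving a 1/f^α spectrum invariant under the geometric
pairing (the h^(α−1) scale factors cancel exactly), so the median
estimates the fractal floor.  Spectra are averaged across windows
*before* the pairing: pairing raw single-window periodograms would
multiply the fractal estimate by E[√(P₁P₂)]/S = (Γ(3/2))² = π/4 ≈ 0.785
(chi-square bias of unaveraged periodograms) and leave a ~20% spurious
"oscillatory" residual at every frequency, whereas the window-averaged
order is asymptotically unbiased — verified by the pure-1/f residual test.
Resampled spectra are evaluated on FFT-fast zero-padded grids and
linearly interpolated onto the 15-s window's grid (≈ 0.067 Hz spacing).
The oscillatory residual is total − fractal, stored with exact
additivity.  Per channel, the individual SO and spindle peaks are the
highest *local* maxima of the residual inside (0, 2] Hz and [10, 17] Hz;
a band with no local maximum is flagged and its global maximum returned
with a warning.

**Event detection.** Spindles: band-pass ±2 Hz around the channel's
individual spindle peak (zero-phase Butterworth, order 3 per pass),
instantaneous amplitude by Hilbert transform, smoothed with a 200-ms
centered moving average; threshold at the 75th percentile of the smoothed
envelope over stage-eligible samples; events are supra-threshold runs of
0.5–3 s, centered on the largest positive peak of the band-filtered
signal within the run.  Slow oscillations: 0.16 Hz high-pass then 2 Hz
low-pass (same filter family); candidates are the spans between
successive positive-to-negative zero crossings containing exactly one
negative then one positive half-wave and lasting 0.8–2 s; candidates
whose trough-to-peak amplitude reaches the 75th percentile of all
stage-eligible candidate amplitudes are kept (percentiles use linear
interpolation between order statistics, and the comparison is inclusive
so exact ties all pass).  Both detectors extract ±2.5-s epochs from the
raw, unfiltered signal (spindles around the positive peak, SOs around the
trough), drop events whose epoch would leave the recording or whose
center falls outside the requested stages (counted in a log), and are
invariant to a global gain change because both thresholds are quantiles
of the ongoing activity.

A consequence worth stating plainly: a fixed-quantile threshold fires on
pure noise.  On event-free 1/f background the spindle detector produces
roughly 4–5 supra-threshold runs of 0.5–3 s per minute at any
signal-to-noise ratio (the exceedance fraction is 25% by construction,
and the 4-Hz analysis bandwidth sets the run-length distribution).  The
criterion is precise only where genuine events dominate the upper
quartile of its reference distribution — which is the situation it was
designed for in real NREM sleep, where sigma-band bursts are the upper
envelope quartile.  Detector-fidelity fixtures therefore plant events at
matching densities (spindles 15/min × 1 s ≈ 25% duty; SOs 3/min against
the ~10–20 candidate cycles/min of low-frequency noise), and the
false-alarm floor on pure noise is documented by its own test rather than
hidden.

**Epoch normalization and co-occurrence.** All detected epochs are
z-scored in the time domain (raw retained), removing amplitude
differences between subjects, ages or amplifiers before phase estimation.
Coupling analyses use only spindles with a same-channel SO trough within
±2.5 s (symmetric window; the nearest such SO is the partner) and are
restricted to NREM3 by default, with an NREM2+3 variant available.

**Phase read-out and coupling strength.** The z-scored spindle epoch is
reflection-padded by its own length, low-pass filtered at 2 Hz
(zero-phase), Hilbert-transformed, and the analytic phase is read at the
epoch center (the spindle peak).  Convention: cosine phase — SO up-state
peak ↦ 0 rad, trough ↦ ±π.  Coupling strength is 1 − circular variance,
i.e. the mean resultant length R = |n⁻¹ Σ exp(iφ)| ∈ [0, 1]; the
preferred phase is the argument of the same mean vector, undefined (an
explicit error) at zero resultant.  R is upward-biased at small n
(E[R] ≈ √π/2/√n under uniformity), so channels with fewer than
`min_events` (default 10) gated spindles are reported as missing rather
than as spuriously strong coupling.

**Time–frequency maps.** SO-trough-locked power (−2…2 s in 50-ms steps,
5–30 Hz in 0.5-Hz steps) from 500-ms Hanning-tapered DFTs per trial,
averaged across trials; time points whose window exceeds the epoch are
NaN.  Baseline correction z-scores each bin against the mean and SD of a
bootstrap distribution (trials resampled with replacement, default
10,000 iterations via multinomial weights) of the trial-averaged power of
each baseline bin (−2…−1.5 s), pooled over iterations and bins per
frequency.  Pooling the bins keeps the scale at a single trial-averaged
bin; note that the observed baseline bins are scored against a
distribution centered on themselves, so their own z spread is shrunk
below 1 (towards √((1−ρ)/(2−ρ)) for bin correlation ρ) — the map is
standardized in the marginal sense, and z is exactly invariant to a
global rescaling of the trials.

**Behavior.** Juggling performance per 3-min block is the number of
three-ball cascades: each uninterrupted run of k consecutive catches
contributes ⌊k/3⌋ (a run below three catches is no cascade; runs are
independent inputs).  Within each performance test the block scores are
fitted by the closed-form least-squares line with block index x = 1…n;
the slope m is the learning curve, and task proficiency y₁ = m + c is the
fit at the first block (exact identity, asserted in the container).
Overnight changes are post-minus-pre differences of y₁ and m across a
retention interval.

**Statistics.** Family-wise error over the montage is controlled by
cluster-based Monte-Carlo permutation: element-wise t values thresholded
at cluster alpha 0.05 (two-sided by default), supra-threshold elements
joined through the channel adjacency into signed clusters (singletons
allowed — the minimum-neighbor requirement is zero), cluster statistic =
member count (max-size criterion), null = distribution of the maximum
cluster size under label exchanges (independent groups), sign flips
(paired), or permutations of the behavioral scalar (correlations), with
the +1-corrected Monte-Carlo p = (b+1)/(n_perm+1).  Correlations are
Spearman rho per channel transformed by t = ρ√((n−2)/(1−ρ²)); |ρ| = 1 is
capped at a large t with a warning.  Partial rank correlations
residualize the rank-transformed variables on rank-transformed covariates
before correlating.  Cluster effect sizes are the mean Cohen's d (pooled
SD) or mean rho over members.  Permutation realizations are made
invariant to the caller's subject ordering by canonicalizing the row
order internally; results are deterministic given the seed.

Channel adjacency is pinned explicitly as the Delaunay triangulation of
schematic 2-D 10–20 positions (24 edges on the 11-channel montage,
including diagonal links), mirroring the triangulation-style neighbor
templates EEG toolboxes default to; a plain distance-threshold variant is
available, and the relation is exported/imported as an editable CSV.  On
a montage this sparse the max-size criterion is intrinsically
conservative: rejection effectively requires an adjacent same-sign
supra-threshold pair, bounding the family-wise error near
24·2·(α/2)² ≈ 0.03 (measured 0.022 for t clusters and 0.029 for rho
clusters at n = 30 over thousands of null repetitions).  Rank
discreteness makes the rho→t threshold additionally conservative below
n ≈ 25, which is why the null calibration of the correlation variant is
run at n = 30.

## Synthetic ground truth

The generator is a verification instrument, not a biophysical model.  A
recording is per-channel 1/f^α Gaussian noise (spectrally shaped white
noise; default α = 2.0, the scale-free exponent reported for NREM sleep,
default RMS 10 µV) plus planted events inside stage-eligible epochs of a
30-s hypnogram built from a stage plan:

- **SO**: one negative then one positive half-wave of a sinusoid at
  `so_freq` (default 0.8 Hz, amplitude 75 µV), trough recorded as ground
  truth; placed on a jittered grid (exact counts, guaranteed minimum
  separation; an infeasible request raises).
- **Spindle**: cosine carrier at the subject's spindle frequency under a
  Gaussian envelope (σ = duration/6, default duration 1 s, amplitude
  20 µV), envelope peak aligned with a carrier peak.
- **Coupling**: a configurable fraction of spindles is attached to
  distinct SOs with the envelope peak placed where the *read-out* phase
  equals a von Mises(μ, κ) draw.  The analytic-signal phase of an
  isolated single-cycle waveform deviates from the idealized linear phase
  by up to ~0.3 rad and spans slightly less than 2π within the cycle, so
  the generator numerically inverts the actual epoch read-out (extending
  the placement slightly beyond the cycle boundaries to cover the full
  circle); the inversion is exact to < 10⁻³ rad.  Uncoupled spindles are
  placed at least 3 s from any SO trough as clean negative controls.
- Default densities (knobs, not claims): SO 4/min and spindles 2/min in
  NREM3.  Fixtures and cohorts override them with stated rationale (see
  above for the detector operating densities).

**Cohorts.** Per-subject κ is uniform on a configurable range (default
[1, 8]); the latent overnight proficiency gain is tied to κ through a
Gaussian copula with Pearson parameter 2·sin(π·ρ_s/6), so the rank
correlation approaches the target (default 0.6) as the cohort grows.  The
overnight learning-curve change is −0.5 times the centered gain plus
noise with half its spread, reproducing the strong inverse
proficiency/curve relation of a dynamic learning process (expected
ρ_s ≈ −0.7).  Block-level cascade counts are integer, truncated at zero,
around the latent linear trend (SD 1 cascade); adults juggle 5 blocks per
test, adolescents 3.  An age split with overlap assigns higher-κ subjects
preferentially to the adult group, giving the pipeline's age contrast a
planted effect.  Cohort nights use a scaled-down stage plan (30 s wake,
20 min N3, 2 min N2 — a consolidated bout instead of full sleep cycles)
with spindles 12/min of which 25% couple to SOs at 3/min, i.e. ~60 gated
events per channel; real nights have more N3 and hence more events, so
the synthetic event counts are conservative for estimator noise.

## End-to-end pipeline

`run_pipeline` simulates the cohort (one or two nights per subject;
adaptation-night seeds are derived from the learning-night seeds),
individualizes and runs both detectors per subject and night, gates and
normalizes the events, computes per-channel coupling, fits the learning
curves, and runs: a two-sided cluster permutation contrast of coupling
strength between age groups; cluster-corrected Spearman correlations of
coupling strength with the overnight changes in task proficiency and
learning curve (one-sided by default — positive for proficiency, negative
for the curve — matching the directional hypotheses of the design; a
two-sided mode is a config switch); and a trait summary correlating
coupling strength between the two nights per channel.  Spectra for peak
finding are capped at 120 windows (~2¼ min of NREM) per night for
runtime, which is ample for the planted peak densities.  A provenance log
(package and numpy versions, full config echo, every per-subject and
per-night seed, statistic seeds) suffices to reproduce a run
bit-identically.  Any stage failure aborts with the stage name and the
offending subject/night.

## What the verification shows — and does not

Passing tests establish that the chain recovers *planted* structure:
fractal exponents within ±0.15, individual spindle peaks within ±0.5 Hz,
detector F1 ≥ 0.85 at matched densities, R within sampling error of
I₁(κ)/I₀(κ), preferred phase within 10° of the planted μ, rank-faithful
κ→coupling-strength mapping across subjects, and null-calibrated
family-wise error control.  The generator's Gaussian background lacks
real EEG's non-stationarity, arousals, artifacts, heavy-tailed sigma
bursts and volume conduction; consequently the detector fidelity and the
cohort power measured here are upper bounds of a particular, stated
regime rather than predictions for arbitrary real recordings.  The
percentile-threshold false-alarm floor quantified above is the main
caveat when transferring detection counts to data whose event densities
are unknown.

## Problem sizes

Simulated problem sizes are chosen as the package's own verification
conditions: 10-min single-channel recordings for spectral recovery,
8-min N3 fixtures for the detectors, 20-subject single-night cohorts
(10 replicate seeds) for the end-to-end recovery, a 12-subject two-night
cohort for the trait/stability summaries, and 200 null repetitions at
200 permutations for the calibration checks.
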