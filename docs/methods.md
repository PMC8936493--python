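# Methods

This note documents the models and procedures implemented in `stagewave`,
the assumptions behind them, the defaults that matter, and what the
synthetic validation does and does not establish.

## The mean-field whole-brain model

Each cortical region is modeled as an infinite pool of Kuramoto phase
oscillators with Lorentzian-distributed natural frequencies (center
`Omega`, half-width `Delta`). The Ott–Antonsen ansatz reduces each pool to
one complex order parameter `z_i = r_i exp(i psi_i)` — modulus 0 means
within-region asynchrony, 1 full synchrony — which stands in for the
region's band-limited analytic signal. Regions interact through the
structural weight matrix `A` (symmetric, zero diagonal, normalized so the
mean over all R^2 entries is 1) with conduction delays
`tau_ij = length_ij / velocity`:

    dr_i/dt  = -Delta_i r_i + (L_i/2) r_i (1 - r_i^2)
               + (G/2R)(1 - r_i^2) sum_j A_ij r_j(t - tau_ij)
                   cos(psi_j(t - tau_ij) - psi_i)
    dpsi_i/dt = Omega_i + (G/2R)(r_i + 1/r_i) sum_j A_ij r_j(t - tau_ij)
                   sin(psi_j(t - tau_ij) - psi_i)

The `G/2R` prefactor is the form the Ott–Antonsen reduction produces when
each oscillator receives between-region input `G A_ij / R` through delayed
regional mean fields; the finite-N oracle (`simulate_micro_oracle`) uses
exactly that per-oscillator scaling, which is why the two agree.

Key parameters (defaults in parentheses):

- `Omega` (2*pi*6 rad/s): theta-band center frequency.
- `Delta` (1 s^-1): frequency spread; also the modulus relaxation rate.
  Without coupling the modulus has the closed-form fixed point
  `r* = sqrt(1 - 2 Delta/L)`, stable when `L > 2 Delta`; this law anchors
  the simulator tests.
- `L` (0.7) and `G` (0.15): local and global coupling, the reference
  configuration for a 68-region empirical connectome. For any *other*
  connectome these must be re-derived with the resting-state grid search
  (below); couplings are not transferable across connectomes.
- `dt` (1 ms): forward-Euler step with a ring of past states for the
  delayed reads; delays are rounded to the nearest step. Convergence is
  first order in `dt`; the modulus is clipped to [0, 1] after each step
  (Euler can overshoot near r = 1), and `1/r` in the phase equation is
  floored at `r_floor = 1e-6` (the phase of a fully desynchronized pool is
  undefined; the floor makes it maximally susceptible to its neighbors,
  which is also the physically sensible limit).

Numerical integration is compiled with numba; cos/sin of the phase buffers
are cached so delayed coupling reads and phase-lag statistics need no
per-edge trigonometry.

### Resting state and metastability

Resting dynamics are characterized by *metastability*: the temporal
standard deviation of the order-parameter modulus, regionally (averaged
over regions) and for the global order parameter. The global order
parameter is the mean of the regions' **unit** phasors (phases only; an
amplitude-weighted variant exists behind a flag). The temporal structure
of global synchrony is summarized by the mean absolute autocorrelation of
its modulus series. `grid_search_resting` simulates replicate runs from
random histories over a (G, L) grid and selects the pair with the best
rank-sum trade-off: high local and global metastability, low
autocorrelation, ties resolved toward the weakest couplings.

## Directed phase-lag connectivity (dpFC)

For analytic signals `z_i`, the cross-spectral convention is
`S_ij = z_i conj(z_j)`, so `Im(S_ij) ∝ sin(phi_i - phi_j)` is positive
when i is phase-ahead of j for lags below pi. The statistic is the average
of `sgn(Im(S_ij))` — with `sgn(0) = 0`, and imaginary parts at the level of
floating-point residue (≤ 1e-12 relative) counted as zero so identical
signals score exactly 0:

- *within-stage*: averaged over the samples of a stage's flat (from the
  first sample after the 5-sample bump to the stage end; the first stage
  has no bump) and then over trials;
- *across-trial*: averaged over trials at each sample, time-locked to a
  stage onset; a trial leaves the average once its stage has ended, and
  the series is truncated with a warning when fewer than two trials
  remain.

The statistic is antisymmetric, bounded by [-1, 1], invariant to common
phase shifts and positive envelope rescaling, and blind to zero-phase-lag
coupling by construction.

Significance uses circular-shift surrogates: each trial x region phase
series is rolled by an independent uniform offset (preserving its
autocorrelation, destroying cross-region alignment), the statistic is
recomputed per surrogate, and a link is significant when its empirical
|dpFC| exceeds the (1 - alpha) per-link quantile of the surrogate |dpFC|
(two-sided via the absolute value). When `(n_surrogates + 1) alpha < 1`
the quantile is unresolvable and the maximum surrogate value is used, with
a warning. No multiple-comparison correction is applied by default; a
Benjamini–Hochberg option exists. For multiple subjects the statistic is
the across-subject mean with subject-wise surrogate shifts. Calibration on
an independent-phase null is part of the validation suite; with 200
surrogates the realized type-I rate sits near the nominal 5% (per-link
quantile estimation from finite surrogates leaves a small upward bias at
smaller surrogate counts).

Band-limiting uses a 4th-order Butterworth (3.8–8.5 Hz cut-offs),
forward-backward for zero phase, and the Hilbert transform; both are
computed on symmetrically padded epochs (0.4 s) with the padding
discarded.

### Local synchrony and envelope changes

Local synchrony is the envelope of the analytic signal, z-scored over each
trial's time axis and averaged across trials time-locked to stage onsets.
The relative envelope change at an onset is the **difference** (z-scores
may be non-positive, so a ratio is undefined) between the mean over the
post window [0, 50] ms and the pre window [-60, -10] ms, both as inclusive
sample sets (at 100 Hz: samples 0..5 and -6..-1).

## Bump HSMM stage segmentation

A trial is a fixed sequence of stages; every stage after the first begins
with a *bump*, a 50-ms (5-sample) multivariate amplitude modulation with a
trial-invariant topology across principal components, shaped by the
half-sine template `w_p = sin(pi (p + 1/2)/5)`. Between bumps the signal
is a zero-mean *flat* whose duration follows a gamma distribution with
shape fixed at 2 and a free per-stage scale, discretized as
`pmf(d) = CDF(d) - CDF(d - 1)` for d ≥ 1 and renormalized over the support
up to the longest trial (the truncated tail mass is negligible for
realistic scales). Emissions are independent unit-variance Gaussians on
z-scored component scores (a global variance can optionally be estimated
instead).

EM alternates an exact E-step — forward–backward dynamic programming over
all admissible non-overlapping bump placements, with the duration
convolutions computed as scaled linear-space FFT convolutions — with
closed-form M-steps: bump magnitudes are posterior-weighted half-sine
projections of the data, and gamma scales are expected flat durations
divided by the shape (expected durations follow from the marginal onset
posteriors by linearity). Training log-likelihood is non-decreasing across
iterations up to the tiny error of the discretized-gamma scale update and
FFT round-off. Multi-start initialization draws magnitudes from N(0, 0.5)
and scales from random partitions of the mean trial length; by default
each start runs 8 EM iterations and only the best start (by
log-likelihood) runs to convergence — the short-run-then-refine strategy
standard for EM initialization — with a flag to run every start to
convergence.

Decoding is per-trial MAP placement by Viterbi dynamic programming; the
MAP log posterior is returned so low-confidence segmentations can be
flagged. Model order is chosen by leave-one-subject-out cross-validation:
starting from the smallest candidate bump count, the next larger model is
adopted only while an exact two-sided binomial sign test (ties dropped,
alpha 0.05) says it fits significantly more held-out subjects better.
Designated stages may carry condition-specific gamma scales (e.g. a
retrieval stage that lengthens with task difficulty).

Preprocessing: 1–30 Hz band-pass, optional per-trial baseline correction,
channel covariances averaged across subjects, eigenvectors retained to a
variance target (default 90%), scores z-scored per component within
subject.

## Targets, fitness, and pulse optimization

A target state set holds, per stage: the signed significant within-stage
dpFC pattern `x` (entries -1/0/+1), the relative envelope change vector,
and the median stage duration. A pulse schedule assigns each region a
signed 30-ms increment of its local coupling at each stage onset, bounded
by `L_max`. Objectives:

    f1 = sum x_i y_i / sum |x_i|          (dpFC sign agreement)
    f2 = Spearman(simulated, target envelope change)
    f3 = (1/L_max) sum_j |dL_j| / sum |x_i|
    f  = f1 - (1 - f2) f3

Simulated dpFC treats a replicate ensemble (default 25) as trials; the
simulated "envelope" is the order-parameter modulus itself. Replicates
share one base initial state plus sigma = 0.01 Gaussian jitter — replicate-
averaged phase-lag signs are only meaningful when replicates share their
phase relationships, mirroring a data-informed initialization. Stages are
evaluated and optimized sequentially; each stage's replicates start from
the terminal samples of the previous stage (of the best individual, during
optimization). A Spearman correlation on a constant vector is returned as
0 with a warning so degenerate candidates cannot crash the optimizer.

Optimization is an island model: islands in a ring, each running
differential evolution with its own (F, CR, variant) setting from a fixed
table interleaving exploratory rand/1 and exploitative best/1
configurations, migrating their best individuals to the ring neighbor
periodically. Greedy replacement makes the best fitness non-decreasing.
The final pick per stage is the individual with minimal `(1 - f2) f3`
among the top-K by combined fitness, which vetoes solutions that buy dpFC
agreement with large, envelope-inconsistent pulses. Every evaluated
individual is archived; ensemble picks sample per-stage pulses uniformly
from the top fraction of the archive (with replacement when the pool is
small).

Initial histories can be built from reference analytic epochs: the modulus
history is the straight line joining the across-trial mean envelopes 0.10 s
and 0.05 s before the first post-stimulus onset (rescaled by the 95th
envelope percentile into order-parameter range, clipped to [0.02, 0.98])
plus sigma = 0.01 noise; phases of regions with significant inter-trial
phase consistency (resultant-length surrogate test) are fixed to their
circular means, the rest are set by a small (1+lambda) evolution strategy
maximizing the fraction of target pre-stage dpFC link signs realized by
the instantaneous lags. Phase histories rotate backwards at the natural
frequency so delayed reads see a consistent oscillation.

## Lesion relevance

A lesion zeroes one (stage, region) pulse while everything else —
including the replicate initial histories — is held fixed; by construction
re-running the full model is bit-identical, so the lesion is the only
difference. Relevance is the fraction of target links matched by the full
model that the lesioned model loses, computed per stage from the same
pre-stage histories. A zero-pulse region is a no-op lesion with relevance
exactly 0. Relevance (all stages x regions pooled) is regressed per
ensemble model on two single predictors: |dL|, and |dL| x log(node
strength + eps) with eps a tenth of the smallest positive strength so
isolated nodes stay finite.

## Synthetic data: what it emulates, and what it does not

`synth_connectome` places regions uniformly in a 140-mm-diameter sphere,
with exponentially distance-decaying weights randomly thinned to a target
density, Euclidean fiber lengths, and mean-1 normalization.

`synth_task_epochs` generates region-space trials: gamma(2) stage
durations, 5-sample half-sine bumps projected from a latent pattern space
through a random orthonormal map, a 6-Hz carrier whose per-stage phase
offsets realize a prescribed region-pair lag structure and whose envelope
steps at stage onsets, plus white noise. The carrier gets a random global
phase per trial: ongoing theta is not stimulus-locked in real recordings,
and a deterministic stimulus-locked carrier would be a confound no
analysis should be expected to survive.

`synth_bump_scores` samples component-space data directly from the stage
model's own assumptions (bumps + flats + white noise, no mixing/filter/
carrier); each bump loads a given magnitude on a small number of random
components. This is the recovery fixture for the segmentation machinery.

`synth_model_fixture` wires up a complete known-truth pulse study: a
16-region connectome; couplings (G = 0.3, L = 2.0) taken from the
package's own resting-state grid search **on that connectome** — the same
protocol as tuning the reference couplings to resting dynamics, because
couplings do not transfer across connectomes; a phase-aligned base history
(link signs then live in small consistent lags, as in data-informed
initializations); and a ground-truth schedule pulsing half the regions
with mixed-sign magnitudes bounded by `L_max = 200`, the largest-magnitude
pulse per stage made negative. Targets are generated from the true
schedule with a plain |dpFC| ≥ 0.5 threshold standing in for surrogate
masking (the truth is known; no surrogates needed).

Two fixture choices deserve emphasis, both consequences of the model's
mechanism rather than conveniences:

- **Pulse scale.** With `Delta = 1 s^-1`, a 30-ms pulse changes the
  modulus at rate ~|dL|/2 per second. Pulses bounded by 20 shift phase
  lags by ~1 mrad and flip no link signs anywhere in the (G, L) plane; the
  switching phenomenon requires pulses strong enough to collapse (or
  boost) a region's synchrony within the 30-ms window, i.e. |dL| of order
  100-200. The `PulseSchedule` default bound remains 20; the fixtures
  declare 200.
- **Sign asymmetry.** Only synchrony-collapsing (negative) pulses re-phase
  a region — as r falls, the (r + 1/r) susceptibility grows and the
  region's phase slews to its local field — so negative pulses carry the
  dpFC-switching load while positive pulses mostly move envelopes. The
  lesion fixture therefore guarantees its largest pulse is negative, so
  the lesion analysis probes a mechanistically active pulse.

What passing these tests shows: the statistics are exact on constructions,
calibrated on nulls, and the estimation/optimization machinery recovers
known ground truth at realistic signal-to-noise. What they do not show:
performance on real MEG, where source leakage, non-Gaussian and temporally
structured background activity, inter-subject topography variability, and
forward-model errors are all absent from the generators. In particular,
the white-noise emission model of the segmentation HSMM is misspecified
under strongly autocorrelated backgrounds: with an ongoing theta carrier
comparable in power to the noise, EM can prefer carrier-matching solutions
with higher marginal likelihood than the generating truth, and onset
accuracy degrades badly. This is a known limitation of the method class,
not of this implementation; on such data the bump topographies and onsets
should be interpreted with care.

## Problem sizes used in the validation suite

Desk-scale sizes, chosen to exercise every code path while keeping the
suite comfortably re-runnable: 16-region connectomes (3 regions with a
5000-oscillator micro oracle for the mean-field check), 10 synthetic
subjects x 20 trials for segmentation (200 trials total), 200 circular-
shift surrogates over 496 links for calibration, 2-stage pulse studies
with 25 replicates, 2 islands x 20 individuals x 40 generations for the
optimizer (5 seeds), 60-s relaxation runs, and 5 x 5 coupling grids with
2 replicates of 60-s resting runs.
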