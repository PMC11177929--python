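# Methods

## The generative model behind the synthetic sessions

Each session simulates a delayed match-to-sample experiment: a 200-ms cue
(one of 4 content conditions), a blank delay, and analysis epochs fixed at
spontaneous [−150, 0) ms, stimulus [0, 200) ms, delay [700, 1700) ms and
later delay [1200, 1700) ms relative to cue onset. All windows everywhere
are half-open `[start, end)` in ms.

Spikes are an inhomogeneous Poisson process discretised to 1-ms bins by
Bernoulli thinning (`p = rate × 1 ms`, at most one spike per bin). The
binary-bin convention matches threshold-crossing multiunit activity and is
what the correlogram sums assume. The rate profile per electrode `e` and
condition `c` is

- baseline `r₀` (default 10 sp/s, a typical V1 spontaneous level);
- stimulus period: `r₀ × gain[e, c]`, default gain levels (6, 4, 2.5, 1.5)
  assigned to conditions by a per-electrode random permutation;
- off-response after cue offset: an exponentially decaying bump
  (amplitude 15 sp/s, time constant 100 ms) — the shape is a modelling
  choice, since only the transient's existence is constrained;
- delay period: `r₀ + δ[e, c]`, default δ levels (+2, +0.7, −0.7, −2) sp/s
  assigned by a second, *independent* per-electrode permutation. Rates are
  clipped at 0 (or raise, when clipping is disabled).

Two defaults deserve justification. The delay offsets are deliberately
small relative to baseline — delay firing sits near spontaneous levels and
content modulation is weak, which is the regime that makes held-out
designation and batching necessary at all. The independence of the delay
ranking from the stimulus ranking is the default because it is the
structure the cross-temporal analyses are designed to detect; an
`equal_ranking_config` helper flips it for contrast tests. A fraction of
trials (default 5%) is marked incorrect, with delay offsets scaled by an
attenuation factor (default 0.25); the attenuation magnitude is a free
knob, as only the direction (weaker modulation on errors) is constrained.

Pairwise synchrony is injected by copying each source spike inside a chosen
epoch onto a target electrode at a fixed lag with probability
`copy_probability`; copies leaving the recording window are dropped and
counted. This gives the connectivity stage an exact ground truth: the
corrected correlogram must peak at the injected lag, in the injected epoch
only.

What the generator does **not** emulate: bursting and refractoriness,
rate drift and slow non-stationarities across a session, electrode
cross-talk, eye-movement covariates, and realistic trial-to-trial
correlation structure beyond Poisson noise. Passing tests therefore
demonstrate correctness of the statistics under their own assumptions, not
robustness to every pathology of chronic recordings — the artifact- and
SNR-filters exist precisely because real data violate these assumptions.

## Preprocessing

MUA events are positive threshold crossings of the absolute high-passed
trace: a sample fires iff it is the first to reach `4.5 × σ̂`, with
`σ̂ = median(|x|)/0.6745` (robust to the spikes themselves; the estimator
choice is ours, as is a 4th-order zero-phase Butterworth 1000-Hz high-pass
helper). Artifact trials are removed when the Iglewicz–Hoaglin modified z
score `0.6745 (x − median)/MAD` of the pooled per-trial rate exceeds 2.5 in
magnitude; with MAD = 0 the ordinary z-score is the fallback, and identical
rates keep everything. Channels are retained when the stimulus-window PSTH
peak *height above the prestimulus mean*, divided by the prestimulus SD,
reaches 5; measuring a height (not an absolute peak) keeps unresponsive
channels excluded no matter how much data is averaged. The PSTH is smoothed
with a 10-ms boxcar first (width exposed in config). Receptive fields are
least-squares 2-D Gaussians; size is reported as `2√(σx σy)` (the axis
combination is unspecified upstream, so the geometric mean is our
convention), fits with r² ≤ 0.6 are excluded from the array centre, and a
non-convergent fit is marked `r² = −∞`.

## CMI

`designate_hl` picks argmax/argmin of per-condition mean rates, breaking
ties by condition-label order and flagging them. `compute_cmi` preserves
the designation's minuend/subtrahend roles, so applying an early-stage or
other-task designation can legitimately produce negative values; electrodes
whose two rates sum to zero return NaN and drop out of aggregates.

Self-designation on the data being evaluated biases the CMI upward (the
argmax chases noise). The cross-validated variant therefore designates on
all but a held-back `1/k` of correct trials per condition (k = 20,
200 iterations) and evaluates on the held-back portion plus
trial-number-matched random subsets of the incorrect and fixation sets.
When incorrect trials are rarer than 5% of the total, the effective fold
count adapts to `round(n_correct / n_incorrect)` so the held-back portion
stays matchable; sets smaller than the matched size clip it with a logged
warning. Fold assignment is seeded and recorded.

Trial-by-trial stimulus/delay correlation is computed within condition and
averaged, so condition-driven rate differences cannot masquerade as
trial-wise coupling. Ranking similarity between epochs uses Spearman's ρ on
per-condition means (≥ 3 conditions required).

## Decoding

Batches average 20 *adjacent* same-condition trials — adjacency read as
acquisition order within condition, with the final partial batch dropped.
Windows are 200 ms wide at a 50-ms step by default. The tuning `fᵢ(θ)` is
the per-condition mean count in the training window, floored at
ε = 0.01 to keep the logarithm finite; per repetition (default 1000;
the drivers and checks here use 100), 15 training batches per condition are
drawn without replacement within the repetition and the remainder is the
test set. Argmax ties are broken uniformly at random under the run seed.
With a flat bias term the decoder is exactly the naive-Bayes Poisson MAP
rule with uniform prior, which the tests assert against a brute-force
posterior. Permutation p-values are one-tailed,
`(1 + #{null ≥ obs})/(1 + n_perm)`, with labels shuffled across batches.
The cross-task harness is intentionally a thin contract around a standard
linear SVM (regularisation chosen on a fixed small logarithmic grid by
3-fold cross-validation, for determinism); only the sampling protocol
(300 trials per condition, 100 iterations, label translation through the
cue–probe pairing map) is bespoke.

## Connectivity

The correlogram is evaluated verbatim — trial-summed coincidence counts
normalised by the geometric mean of the two units' total counts — with no
triangular correction for finite windows; the flank bias that omission
introduces is absorbed by the jitter subtraction. The numerator is computed
by FFT cross-correlation and rounded back to integers for binary trains, so
it equals the naive triple loop exactly. Jitter resampling permutes bins
within consecutive 25-ms blocks per trial (a shorter final block is
permuted within itself), preserving per-trial block counts exactly and
hence the across-trial PSTH at block resolution; three Monte-Carlo rounds
are averaged by default, and an exact-expectation mode (products of
block-uniform densities) serves as a deterministic oracle. Blocks are
aligned to the epoch start (origin configurable). Significance compares the
corrected CCG's maximum over lags 1–20 ms against 7 × the SD of the
*corrected* values at |τ| ∈ [20, 40] (the corrected-flank choice is ours),
with a strict inequality and a degenerate rule (peak > 0) when the flank SD
is zero. Category proportions use the count of stimulus-significant pairs
as denominator and are flagged undefined when that count is zero.

## Association stages and trajectories

Early stage: the shortest session prefix accumulating 1000 correct trials.
Late stage: the longest suffix whose unweighted mean accuracy stays ≥ 90%,
walking backward from the last session; the session whose inclusion breaks
the bar is excluded (an `include_breaking_session` flag restores it, since
the backward rule is ambiguous on that point). Stage contrasts freeze the
early-stage h/l designation and compare later-delay CMIs against the
color-color and orientation-orientation reference tasks via |ΔCMI|;
statistics are always computed on raw electrode values, never on smoothed
projections. The PCA projection fits components on the pooled early+late
CMI matrix (time points as samples, per-electrode mean over pooled time
removed — centering is our choice), projects any requested dataset onto the
first three components, then interpolates to a 10-ms grid and smooths with
a 100-ms boxcar *after* projection.

## Numerical and reproducibility choices

All stages accept explicit seeds; identical configuration (including seed)
reproduces byte-identical sessions and output tables. Run configurations
hash their analysis parameters (not output paths) into every artifact
together with the schema version and seed. Degenerate inputs fail loudly:
constant traces, empty epochs, single conditions, silent units, and
insufficient batches raise with the offending item named.

## Problem sizes

The shipped drivers and checks run at desk scale: 8–12 electrodes,
60–500 trials per condition, 100 decoding repetitions and ~10³
pair-condition correlogram evaluations — sizes chosen so every stage's
statistical claims (chance levels, false-positive rates, recovery of
configured effects) are testable in minutes while leaving the full-size
constants (1000 repetitions, months-scale trial counts) available through
configuration. Headline magnitudes measured on recorded cortical data
depend on effect sizes this generator does not calibrate to, and are not
reproduced here.
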