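# Methods

## The generative model

A session presents every combination of grating orientation θ (axial,
period 180°) and spatial frequency φ (cycles/°) on a lattice; the default
lattice is 0–165° in 15° steps × 0.02–0.30 cycles/° in 0.02 steps
(180 stimuli). Each neuron's response on one presentation is an event
count. A tuned neuron carries a 2-D Gaussian tuning surface

    R(θ, φ) = A / (2π σθ σφ √(1−ρ²)) · exp(−q / (2(1−ρ²))) + B
    q = dθ²/σθ² + dφ²/σφ² − 2ρ·dθ·dφ/(σθσφ)

with dθ the orientation difference wrapped to (−90°, 90°], A an integrated
amplitude in events, B the baseline event rate, and ρ the orientation/s.f.
correlation of the bump. On each presentation the neuron is *responsive*
with probability `reliability` (Bernoulli gating of the whole bump); counts
are Poisson around `B + bump` on responsive trials and around `B`
otherwise. The gating matches the all-or-none character of the reliability
statistic (fraction of trials clearing a fixed threshold): unreliable
neurons fail whole trials rather than responding weakly on all of them.

Poisson is the minimal count-noise model; trial-to-trial variance of real
event counts may exceed the mean, so a variance-inflation factor v ≥ 1 is
exposed (`variance_inflation`; gamma–Poisson mixture with variance v·μ).
The default is v = 1.

Multi-session experiments evolve a base population through a schedule:
each session may perturb preferred orientations by wrapped Gaussian jitter
(orientation is axial data, so jitter is applied on the 180° circle),
perturb preferred s.f. by clipped Gaussian jitter, scale reliability, or
*rebound* (reset tuning to the first session's values). The default
four-session schedule emulates a dark-exposure design: baseline 1,
baseline 2 (ongoing drift: 10° orientation jitter), post-dark-exposure
(reduced drift, 3°, and reliability × 0.6), and a recovery session that
rebounds. The jitter scales were chosen once so that the control interval
shows a clearly non-zero median preference shift while the dark-exposure
interval is visibly stabilized; the reliability multiplier 0.6 produces a
reliability drop of the size that visibly degrades decoding without
silencing neurons.

What the generator does **not** emulate: noise correlations between
neurons, slow within-session nonstationarity, response adaptation,
stimulus-onset dynamics, or non-Poisson heavy tails. Passing tests
therefore demonstrate correctness of the estimators under the stated
model, not robustness to every property of real recordings.

## Preprocessing

* **Response window**: per presentation, the response is the mean event
  count over the frames whose interval [t, t + 1/rate) overlaps the
  194–320 ms post-onset window (the latency band where the
  stimulus-triggered event rate peaks). At the typical 15.5 Hz acquisition
  rate this selects onset-relative frames {3, 4}. The overlap rule is one
  deterministic reading of the millisecond bounds; it degenerates to the
  single onset frame when the window is narrower than a frame.
* **Trial exclusion**: any trial flagged for locomotion or eye blink is
  dropped; a stimulus losing all trials is an error. Retained counts are
  tracked per stimulus; downstream code treats NaN-padded entries as
  missing.
* **Responsivity screen**: one-way ANOVA per neuron with stimulus identity
  as the factor; default α = 0.01. Neurons with degenerate (zero-variance,
  equal-mean) data receive p = 1. The screen is a gate, not an endpoint.
* **Deconvolution**: greedy L0 matching pursuit under
  `f = s * k + β·p + b` with a causal single-exponential kernel
  (τ = 0.7 s by default, typical for a slow indicator; only event
  amplitudes are fit, not the kernel shape). Events are added at the
  residual-correlation maximum while the RSS reduction is positive; β and
  b are refit by least squares after each event; iteration stops when the
  residual variance reaches the noise-variance estimate (MAD of the first
  differences of the trace, scaled by 1/√2) or at a hard cap of 5 events
  per second of trace.

## Tuning estimation

Fits are to *single-trial* responses, so the R² statistic rewards
trial-to-trial consistency, not just a well-shaped mean surface. Numerical
choices:

* Bounds: A ≥ 0 (dips are outside the model's intent), B ≥ 0 (events),
  μφ within the presented s.f. range, σθ ∈ [1°, 180°],
  σφ ∈ [0.001, range width] cycles/°, |ρ| ≤ 0.99 (keeps 1−ρ² away from 0).
  μθ is optimized unbounded and reported mod 180, avoiding boundary
  artifacts at 0/180.
* Initialization: preferred orientation from half the complex phase of the
  doubled-angle vector sum of the orientation-marginal means (exact for
  cosine tuning); preferred s.f. from the maximal trial-mean response at
  the nearest grid orientation (ties to the lower s.f.); baseline from the
  minimum stimulus mean; amplitude from the peak-minus-baseline height.
  A uniform (zero-resultant) orientation profile has no defined
  preference and raises; the fitter then falls back to the argmax
  stimulus.
* Orientation periodicity: the Gaussian is non-periodic in θ; residuals
  (including the ρ cross-term) evaluate dθ wrapped to (−90°, 90°], the
  natural treatment for axial data. The literal non-periodic form is
  available via `wrap=False`.
* The solver is trust-region-reflective least squares with an analytic
  Jacobian; R² = 1 − SSres/SStot over all trial-level points. Fits that
  fail to converge are flagged and excluded from tuned pools.

**Permutation significance.** Stimulus labels are permuted across all
(stimulus, trial) observations jointly and the full fit repeated per
permutation (default 1000; calibration experiments use 200); a neuron is
tuned when its observed R² exceeds the null's 95th percentile. Each null
refit re-derives its initialization from the permuted data: giving every
arrangement identical treatment makes the test exact under
exchangeability. (Reusing the observed initialization, superficially a
harmless economy, measurably inflates the false-positive rate — the
observed arrangement alone starts from an initialization tuned to itself —
so it is only available as an option.)

**Bandwidths.** The half-width at half-maximum is reported, by default, by
the conventional printed formula BW = 2·ln(2)·σ (`"as-printed"`); the
mathematically exact Gaussian HWHM √(2·ln 2)·σ is available as
`"hwhm-exact"`. The two differ by a constant factor ≈ 1.177, so deltas and
comparisons are unaffected by the choice.

**Stability.** Between-session deltas are computed only for neurons
significantly tuned and converged in *both* sessions (excluded otherwise,
never zero-filled); Δμθ is the wrapped distance in [0°, 90°], the other
three features are absolute differences.

## Population metrics

Signal correlation is the Pearson correlation between two neurons'
stimulus-averaged response vectors; similarity between two sessions'
matrices is the Pearson correlation over the vectorized strict upper
triangles — the diagonal is excluded because self-correlations are
identically 1 and would inflate agreement. Reliability is the fraction of
preferred-stimulus trials at least 2 baseline SDs above the gray-screen
baseline mean; "preferred stimulus" is the grid point nearest the fitted
(μθ, μφ), with wrapped orientation distance. A degenerate all-zero
baseline makes the threshold 0, in which case any positive response
counts.

## Decoding and drift

Trials are divided into sets of one response vector per stimulus (sets =
trials per stimulus; surplus trials are subsampled with the run seed).
Each set is held out in turn and its vectors classified by the majority
label among the k = 4 nearest (Euclidean) vectors of the other sets,
keeping the neighbor pool balanced across stimuli. Tie-breaking is
deterministic: distance ties resolve by lower set index then lower
stimulus index; vote ties go to the tied class with the nearest member.
Chance is 1/n_stimuli (0.0056 full set; 0.0167 / 0.0083 for the 60-low /
120-high s.f. split at the 0.1 cycles/° boundary). Before cross-session
comparisons, neuron identities are reduced to the tracked intersection and
trial counts matched to the minimum by seeded subsampling.

Fixed-classifier drift trains on one session: acc_X1 is the within-session
set-based CV accuracy; acc_X2 classifies every test-session vector against
*all* training vectors (no set exclusion — the classifier is fixed);
drift = acc_X2 − acc_X1. When the test session is the training session
itself, acc_X2 is computed with the same self-excluding CV and equals
acc_X1 exactly.

## Statistics

The two-proportion Z-test uses the count-weighted pooled proportion,
SE = √(p̄(1−p̄)(1/n₁+1/n₂)), and a two-sided normal p-value (sidedness is a
package choice). Benjamini–Hochberg adjustment delegates to statsmodels;
family sizes larger than the supplied p-values are honored by padding with
p = 1, which preserves the supplied values' ranks. Rank-sum contrasts
report the classic rank-sum W statistic (exact for small samples) with the
Mann–Whitney two-sided p-value; paired-t contrasts with identical pairs
are undefined and reported as no difference.

## Problem sizes used in calibration runs

The acceptance script and the calibration tests size their experiments as
follows (chosen as the smallest sizes at which the Monte-Carlo error of
each check is well below its decision band): chance decoding on 30
neurons × 15 trials × 180 stimuli; permutation type-I on 500 null neurons
× 200 permutations on a reduced 4 × 3 lattice with 4 trials (the test is
exact under exchangeability at any lattice size, so the reduced lattice
only changes cost, not calibration); orientation recovery on 200 neurons
at 25 trials on the full lattice; ANOVA calibration on 10⁴ null neurons;
drift calibration on 20 seeded session pairs of 36 tracked neurons × 25
trials.

## Known limitations

* The deconvolution fits event amplitudes against a fixed kernel shape;
  kernel mis-specification biases amplitudes (not times, to first order).
* The permutation screen refits the full model per permutation with a
  capped iteration budget; the cap trades a little power for runtime but
  cannot inflate the false-positive rate (both sides of the comparison
  share it).
* Reliability compares response-window counts against gray-screen counts
  binned at the same width; slow baseline drift within a session is not
  modeled.
* The greedy mask matcher is order-dependent only through exact overlap
  ties, which are resolved deterministically by id.
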