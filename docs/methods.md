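# Methods

`boutwise` analyzes extracted single-cell calcium fluorescence traces
recorded while an animal consumes a reward, and asks three questions: which
cells are coupled to consumption, how stable that coupling is across
sessions, and whether the population as a whole carries a decodable
consumption code. Because such recordings are rarely public, the package
ships a forward model that generates sessions with planted, exactly known
structure; every analysis is validated by recovering what was planted.

## Session model and synthetic data

A session is a cells × frames fluorescence matrix plus a bout track:
half-open `[start, end)` intervals in seconds, and a phase boundary
separating a habituation period from a stimulus period. Two paradigms are
built in: 10 min of habituation followed by 10 min of free consumption
(bouts sampled in the stimulus phase only), and a 10-min two-administration
paradigm with 1-min deliveries starting at minutes 1 and 6, whose first
minute serves as the baseline window. Frame `f` at rate `r` covers
`[f/r, (f+1)/r)`; a frame belongs to a bout iff its start time falls inside
the interval. The default frame rate is 10 Hz and is always carried
explicitly in configuration — delimited trace files do not embed it.

The generator plants three archetypes. Each cell fires as an inhomogeneous
Poisson process with baseline rate λ (default 0.2 events/s) multiplied by a
bout gain inside bouts: gain > 1 for positively coupled cells (default 2.5),
gain < 1 for suppressed cells (default 0.2), gain = 1 for neutral cells.
Suppression is a multiplicative gain rather than a negative rate so rates
stay nonnegative. Events are convolved with a causal double-exponential
indicator kernel, `h(t) ∝ exp(−t/τ_d) − exp(−t/τ_r)` peak-normalized to
amplitude 1, with τ_rise = 0.07 s and τ_decay = 1.0 s (fast-rise, ~1 s
decay kinetics typical of GCaMP6m); Gaussian noise (SD 0.1) is added.
Free-consumption bouts alternate with rests, both log-normal (consume
median 3 s, σ=0.5; rest median 8 s, σ=0.6, floors at 0.5 s), giving roughly
a quarter of the stimulus phase inside bouts; no quantitative bout
statistics exist for the recordings being emulated, so these are declared
fixture defaults, not estimates.

Planted label counts are deterministic (largest-remainder rounding of the
configured fractions) and, in longitudinal cohorts, so is the number of
shared cells (`round(overlap_rate · n)`) and of label switchers
(`round(switch_prob · n_shared)`), with the identity of switchers and their
new labels random. Planting counts rather than Bernoulli draws removes
binomial jitter from the recovery targets without changing what the
analyses see. Event and noise streams are drawn per phase from named child
seeds, so the habituation segment of a trace is bit-for-bit independent of
anything configured in the stimulus phase (the convolution is likewise run
per segment; the causal kernel lets habituation transients bleed forward,
never backward).

Seeding everywhere follows one scheme: a single root seed per run, with
each stage deriving `SeedSequence([root, blake2s(stage_name)])`, so stages
can be re-run independently and reproduce a full-pipeline run exactly.

## Activity metrics

Traces are z-scored per cell against a baseline window — by default the
habituation phase of the same session (whole-session baseline is available
by passing an explicit window; the two-administration paradigm uses its
first minute). Cells with zero baseline SD are flagged degenerate, zeroed,
and excluded downstream. Events are maximal runs of z above
`k_mad · MAD/0.6745` (k_mad = 3) lasting at least 0.3 s; a cell is active
in a phase iff at least one event intersects it. These thresholds are
declared conventions — an "active cell" has no standard definition — and
are configurable. Phase contrasts emit paired per-cell means restricted to
cells active in either phase (policy configurable to include all cells).

## Ensemble classification

The bout regressor is the binary per-frame bout indicator, optionally
convolved with the same calcium kernel as the simulator to match indicator
blurring (off by default). Each cell's Pearson correlation r with the
regressor is tested against a circular-shift null: the trace is rotated by
a shift drawn uniformly from `[min_shift, T − min_shift]` frames
(min_shift = 10 s) and r recomputed; rotation preserves the trace's
autocorrelation, which an i.i.d. frame shuffle would destroy and thereby
overstate significance for slow calcium signals. All-shift correlations are
obtained in O(T log T) via circular cross-correlation (FFT), so exhaustive
enumeration of the null is cheap and is used to validate the sampled
version. The two-sided p uses the add-one estimator
`p = (1 + #{|r_perm| ≥ |r_obs|})/(n_perm + 1)` (support `k/(n_perm+1)`,
never 0). A cell is positive if `p ≤ α` and r > 0, negative if `p ≤ α` and
r < 0, else neutral; α = 0.05 and n_perm = 1000 by default. No
multiple-testing correction is applied by default because the readout is
ensemble fractions, not per-cell claims; a Benjamini–Hochberg switch is
provided. Sessions without bouts return all-neutral with a warning. Shift
draws are data-independent, so negating every trace swaps
positive↔negative labels exactly.

## Longitudinal stability

Cells followed across two sessions (via the longitudinal identity map)
contribute one ordered label pair, earlier session first; pairs are not
symmetrized because, e.g., negative→neutral and neutral→negative are
distinct transitions. Stable (generalizer) pairs are pos–pos and neg–neg;
the six switching categories are unstable (specializer). Neutral–neutral
pairs are excluded from both numerator and denominator — the two reported
fractions are complementary on that declared denominator — and the
exclusion is recorded in the output; with every pair neutral–neutral the
fractions are a `None` sentinel, never a fabricated number. The 3×3 count
table exports to a chord structure whose edge sums equal each session's
marginal label counts. Per-animal fractions are compared across groups with
the test-selection policy below.

## Embedding and decoding

The embedding is a deliberately minimal time-contrastive encoder: a
two-layer perceptron (hidden width 32) over flattened 5-frame sliding
windows of the standardized population matrix, trained with an
InfoNCE-style loss in which each anchor's positive is drawn by temporal
proximity (uniform offset up to 10 frames) — and, in hybrid mode, half the
time by shared behavior label — with the batch's other positives as
negatives; similarity is negative squared Euclidean distance at unit
temperature, optimized with Adam. Defaults follow the published
configuration for this model family (latent dim 3, offset-5 windows,
time-delta conditional, hybrid on, batch 800 within the 600–1200 range,
learning rate 1e-4, 8000 iterations); tests and the acceptance script train
with 800 iterations at learning rate 1e-3 and batch 600, which reaches
clear bout structure on the synthetic sessions at desk scale. A
training-free fallback (`encoder='window'`) returns the windowed features
themselves, clipped to `latent_dim` columns when smaller — evaluation
harness behavior can thus be tested with no optimization in the loop (pass
a large `latent_dim` to keep all features).

Decoding uses a 100-tree random forest on a random 70/30 split (resampled
up to 20 times if a side lacks a class). Every accuracy is reported with
two controls: the trained forest re-scored against uniformly permuted test
labels (1000 permutations by default; the mean has the closed form
`Σ_c n_pred(c)·n_true(c)/n²`, used as an oracle in tests; a block
permutation is available for autocorrelation-aware nulls), and the
out-of-bag error for the real labels versus forests trained on shuffled
labels (5 shuffles by default). Cross-behavior transfer trains the encoder
on behavior A's shared-cell traces, applies it frozen to behavior B, and
re-trains the decoder on B's embedded points (carrying A's decoder over
instead is available behind a flag). Across-animal decoding pools
per-animal embedded points with an animal-stratified 70/30 split.

## Closed-form quantifications and test policy

Corrected total fluorescence is
`CTF = integrated_density − roi_area × background_mean`; replicate CTFs of
a region are averaged and divided by the injection-site CTF (exactly one
injection row is required). Negative CTFs are kept and flagged, not
clipped, since clipping would bias rankings. The place-preference index is
percent time in the stimulation-paired chamber; the flavor-preference index
is preferred/(preferred + least), undefined (sentinel) when both intakes
are zero. Epoch tables for alternating light OFF/ON designs must be
contiguous and non-overlapping and aggregate to per-epoch, ON-sum and
OFF-sum amounts.

Two-group comparisons gate on Shapiro–Wilk at α = 0.05 per group: both
normal → two-tailed t-test (paired or unpaired), any failure →
Mann–Whitney U (unpaired) or Wilcoxon signed-rank (paired). Cohen's d
(pooled-SD form unpaired, SD-of-differences paired) is reported regardless
of branch. Degenerate inputs (zero variance in both groups, or identical
pairs) return an explicit degenerate report with p = 1 at the null rather
than delegating to tests whose assumptions fail.

## What the synthetic data do and do not show

The generator reproduces the statistical structure the analyses assume —
bout-locked rate modulation, indicator-blurred transients, additive noise,
partial cross-session overlap with label switching — and therefore
validates the estimators: fraction recovery, null calibration, transition
recovery, decoding contrast against shuffles. It does not emulate neuropil
contamination, motion artifacts, crosstalk between nearby ROIs,
non-Poisson burstiness, slow drift, or behavior-correlated confounds other
than the bouts themselves. Passing tests therefore demonstrate correctness
of the machinery under the stated model, not robustness of the biology
claims to those real-data complications. Problem sizes in the test suite
and acceptance script (e.g. 300-cell sessions for classification recovery,
25–50-cell sessions for decoding and embedding, 200 matched cells for
stability) are the package's chosen validation scales: large enough that
the ±5-point recovery bands are meaningful, small enough to run routinely.

## Numerical choices and edge cases

FFT-based shift correlations agree with direct brute force to ~1e-14 and
exactly reproduce its permutation p on the test fixtures. `fftconvolve`
leaves ~1e-17 residue on exactly-zero traces; the simulator snaps
|values| < 1e-12 to zero so noiseless fixtures are exact. Zero-SD baselines,
constant regressors (no bouts), all-neutral–neutral transition tables, and
both-zero intake pairs each have an explicit path (degenerate flag, warning
+ all-neutral, sentinel, sentinel) rather than NaNs. The permutation p is
never 0 by construction; α = 0 therefore labels everything neutral.

## Known limitations

The contrastive trainer is single-threaded NumPy and makes no attempt at
parity with published embedding tools — it exists so the
structure-vs-shuffle and decoding harness can be exercised end-to-end. The
forest's OOB error is only defined on the training split. The longitudinal
map is taken as input (produced upstream by acquisition software);
image-based cross-session registration is out of scope, as are ΔF/F
extraction, motion correction, spike inference, and figure rendering beyond
serializable chord/plot data.
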