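# Methods

## The problem

A DNA-polymerase "ticker tape" recorder stores a time-varying analyte —
here, neural calcium — as misincorporations along a growing DNA strand.
Sequencing recovers which nucleotides are errors, but not *when* each
nucleotide was written: the record has an index axis (position on the
strand) where every other recording modality has a time axis.  `tickertape`
simulates the recorder's generative model end-to-end and estimates the
missing incorporation times by aligning the binary error strand against
time-indexed predictions of calcium derived from observed experimental
covariates, then re-infers the neuron's tuning from the time-stamped
record.

## Generative model

The unobserved calcium trace is `C = c_1..c_T` on a 1 ms clock.  A neuron's
tuning maps covariates to an expected firing rate: either linear in a
scalar stimulus, `lambda_t = m I_t + lambda_min` (defaults `m = 0.05`
spikes/ms per unit stimulus, `lambda_min = 0`), or speed-scaled cosine
direction tuning,
`lambda_t = lambda_min + (lambda_max - lambda_min)(v_t/v_ref)(1 + cos(phi_t - theta))/2`
(defaults 10 and 150 spikes/s).  Spikes are Bernoulli per 1 ms bin and
calcium is spikes convolved with a causal exponential kernel of decay
`tau = 200 ms` and peak 1 (implemented as the exact recursive filter, which
equals the truncated-kernel convolution up to error < e^-10).

The polymerase has two pieces of physics:

* **Error transfer function** — a sigmoid
  `f(c) = r_max / (1 + exp(b (c - c0)))` with ceiling `r_max`, steepness
  `b`, and half-maximum concentration `c0`.  As written the curve
  *decreases* with calcium for positive `b`; experiment presets use
  `b = -1` so error rates rise with calcium, which is what the
  tuning-inference step assumes.  Because `c0 = 0` in the presets, every
  calcium trace is standardized (zero mean, unit variance) before `f` is
  applied, placing the half-maximum at the trace midpoint and giving the
  sigmoid its dynamic range.
* **Kinetics** — the interval between incorporations is the mixture
  `U ~ p_pause Exp(pause_mean) + (1 - p_pause) Gamma(shape, scale)`.  The
  preset recorder uses `p_pause = 0.001`, 2 s mean pauses and a
  Gamma(1, 10 ms) extension: a ~100 Hz effective rate spending ~17% of
  recording time paused (`p_pause * pause_mean / E[U]`).

A record is generated by drawing a start time from a uniform prior over
the first quarter of the window, accumulating mixture intervals, and
flipping a Bernoulli coin with probability `f(c)` at each incorporation.
Records stop at the configured strand length or at the window edge,
whichever comes first (truncated records are returned with a warning).
Strands serialize to TSV or to template/copy FASTA pairs (errors are
non-Watson-Crick substitutions).

## Alignment

The aligner maximizes the accumulated score

    S[1, t] = A[1, t]                  (+ optional start-time log prior)
    S[n, t] = A[n, t] + max_j [ (1 - w) S[n-1, t-j] + w ln P(step = j) ]

over strictly increasing paths, where `A[n, t]` is the local log-likelihood
of strand element `n` having been written at template time `t`, the lag
`j` ranges over a bounded backward window, and `w` (omega) weighs the
kinetic prior against accumulated similarity (presets: 1/100 for the
stimulus experiments, 1/240 for center-out).  Because row `n` depends only
on row `n-1`, all cells of a row can be computed concurrently; the package
ships a vectorized engine and a plain-loop reference engine that agree to
1e-12, and the test suite checks the dynamic program against exhaustive
path enumeration on small instances.  Ties break toward the smallest lag
and the earliest final time, so paths are fully deterministic.

For production use the template is decimated to `L_C = 50 ms` block means
and the strand is binned into `L_D` nucleotides per row (100 for the
stimulus experiments, 25 for center-out), with binomial count likelihoods;
bin-level times are interpolated back to nucleotides (linear between bin
midpoints, strict increase enforced at one decimated sample period shared
across the `L_D` nucleotides of a bin).

Two numerical choices matter and are this package's own design:

* **Step prior and kinetic band.**  A binned step advances `L_D`
  incorporations, so its prior is the `L_D`-fold convolution of the
  interval mixture, computed exactly in log space by conditioning on the
  binomial pause count (tails stay finite and correctly ordered).  The
  searchable lags are restricted to the central [q0.05, q0.95] quantiles
  of that distribution, inside an outer window spanning at least the
  configured `k` (2000 ms in the presets) and at least the distribution's
  upper quartile.  The restriction is an Itakura-style band derived from
  kinetics: with omega as small as 1/100 the prior's *values* contribute
  almost nothing, so the *support* is the only effective kinetic
  constraint, and leaving implausibly fast or slow steps searchable lets
  the optimizer assemble spurious high-similarity paths anywhere in the
  window (measured: ~50% of 2.5 kbp records misplace globally with a
  one-sided window).  Steps that genuinely fall outside the band — bins
  containing a rare long pause — are absorbed over the following bins,
  costing a transient timing offset.  Single-nucleotide steps keep the
  literal `[1, k]` window, and `extend_search_window=False` restores it
  for binned steps too.
* **Noise-marginalized similarity.**  The template is the *expected*
  calcium; the recorded strand was driven by expected calcium plus
  spike-driven noise passed through the same kernel.  In standardized
  units the true calcium is approximately `a c_template + s Z` with
  `a = sd(mu)/sd(total)` and `s^2 = 1 - a^2` computed analytically from
  the template's rate trace (`var_eta = mean(lambda(1 - lambda)) * sum
  kernel^2`).  The per-nucleotide error probability is marginalized over
  `Z` by Gauss-Hermite quadrature (21 nodes), and in binned mode `Z` is
  treated as shared within a bin — a mixed binomial — because a bin's
  nucleotides are written within a fraction of the calcium correlation
  time.  Without this the plain binomial over-penalizes the true path at
  extreme template values and most records misplace; with it, 5 kbp
  records lock to ~1.3 s median RMSD.  The low-level similarity builders
  default to the plain model (`noise=None`).

Template selection aligns a strand to each member of a template ensemble
(for center-out: eight cosine tunings at uniformly spaced preferred
directions) and keeps the maximum-likelihood alignment, ties to the lowest
id.

## Inference from aligned records

* **Timing accuracy** — RMSD between true and estimated times, in seconds;
  the conventional `sqrt(mean(sq))` by default, with the
  `sqrt(sum)/N` variant available as `variant="as_printed"`.  Timing error
  distributions are heavy-tailed (an alignment either locks onto the right
  part of the window or misses entirely), so medians and means are
  reported side by side and differ by orders of magnitude at small record
  lengths.
* **Tuning strength** — error indicators are grouped into 20 equal-count
  bins by covariate value at the estimated times; bin error rates are
  inverted through `f^-1` to calcium levels and regressed on the
  covariate, and the slope is reported as a ratio to the ground-truth
  calcium-covariate slope (obtained by regressing the true calcium trace
  on the covariate).  Bin rates outside `(0, r_max)` are clipped inward
  with a logged warning.
* **Preferred direction** — a logistic GLM of the per-nucleotide error
  indicator on x/y hand velocity at the estimated times (`theta*` is the
  angle of the velocity coefficients); the error strand is binary, which
  is why the error-count model is Bernoulli.  Ground truth is a Poisson
  GLM of 1 ms spike counts on the same velocities, with McFadden
  pseudo-R^2 (`1 - ll_model/ll_null`) as the fit measure.  Population
  analyses filter to mean rate > 20 spikes/s and pseudo-R^2 > 0.05.
  Angular errors are wrapped to [0, pi].
* **Patch shuffling** — all streams (kinematics and spikes) are cut into
  aligned 2 s patches, one shared permutation is applied, and a trailing
  partial patch stays in place; downstream calcium, templates, and
  records are rebuilt from the shuffled session, probing how the task's
  temporal regularity drives 180-degree confusions.
* **Uncertainty** — percentile bootstrap CIs of means or medians.

## Synthetic center-out kinematics

The published center-out analyses used a recorded primate dataset that is
not redistributable; the package instead generates synthetic sessions that
emulate its statistical structure: out-and-back minimum-jerk reaches to 8
uniformly spaced targets (600 ms reaches, 400 ms holds, 0.5 m/s peak
speed), block-randomized target order, and a speed gate keeping samples
with hand speed in [0.05, 0.4] m/s, concatenated onto a fresh clock.  The
default 384 reach cycles leave ~230 s of gated session, enough for a
12,000 bp record plus its start-time prior.  What the synthetic stand-in
does *not* carry over from real data: trial-to-trial kinematic
variability, non-cosine tuning, shared population dynamics, and
measurement noise on hand position — so passing tests demonstrate the
method's behaviour under its own model assumptions, not performance on
real recordings.  The published per-neuron numbers from the external
dataset are correspondingly out of scope here.

## Experiment harnesses and scales

`run_parameter_sweep` sweeps one polymerase property (record length,
incorporation rate, sigmoid steepness, or maximum error rate) over a grid,
simulating, aligning to the true-tuning template and scoring each trial;
`run_center_out` runs the synthetic reaching study with optional
patch-shuffled and pause-free arms.  All randomness flows through
generators keyed by `(master seed, arm, trial)`, so identical configs give
byte-identical tables and any trial can be reproduced alone.  Default
trial counts are desk-scale (20 per grid point; the published studies used
50–100), and `full=True` (or `--full` on the CLI) restores publication
scale.  The bundled test suite runs further-reduced sessions (e.g. 256
reach cycles and 6 kbp records for center-out properties) chosen to keep
the whole suite under a quarter hour on one CPU.

## Known limitations

* Global alignment is bimodal: a record either locks (timing error well
  under the stimulus feature scale) or misplaces entirely; short records
  (~1 kbp) usually misplace.  Mean RMSD is therefore a poor summary at
  small lengths; medians are reported alongside.
* The kinetic band trades pause representation for search rigidity; a
  record in which pauses dominate the duration (p_pause >~ 0.01 at
  L_D = 100) cannot be tracked by any window compatible with the preset
  `k`, and alignment quality degrades accordingly.
* The noise-marginalization statistics assume stationary spike-noise
  variance; strongly non-stationary rates would call for a time-varying
  noise scale.
* Insertions, deletions, polymerase drop-off, sequence-context-dependent
  pausing, and nucleotide-specific error spectra are out of scope; errors
  are binary substitutions.
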