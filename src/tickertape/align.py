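"""Nucleotide-time alignment: a parallelizable step-pattern DP.

The aligner places each element of a binary error strand (or each bin of
errors) at a template time, maximizing accumulated log-likelihood under a
step pattern that (1) forces strictly increasing times, (2) assigns each
element exactly one time, and (3) bounds the backward search by a window k.
The recursion for the accumulated score S is

    S[0, t] = A[0, t]                      (optionally + a start-time prior)
    S[n, t] = A[n, t] + max_{j in 1..J} [ (1-w) * S[n-1, t-j] + w * lp[j] ]

where A is the local log-likelihood matrix, lp the log kinetic lag prior,
and w a weight balancing local similarity, accumulated similarity, and
polymerase kinetics.  Because S[n, .] depends only on row n-1, all cells of
a row can be computed concurrently -- the row-parallel contract that
distinguishes this step pattern from classic DTW.  Both a vectorized
(default) and a plain-loop engine are provided; they agree to floating
round-off.

A traceback over stored backpointers recovers the maximum-likelihood path,
ending at the most likely final time.  Ties break toward the smallest lag
(latest predecessor) and the earliest final time, so paths are
deterministic.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import gammaln, logsumexp

from .dnap import ErrorFunction, KineticModel, LagPrior, step_log_pmf
from .traces import TimeTrace

__all__ = [
    "AlignmentConfig",
    "Alignment",
    "InfeasibleAlignmentError",
    "PROB_FLOOR",
    "build_similarity",
    "build_binned_similarity",
    "bin_errors",
    "decimate_template",
    "accumulate",
    "traceback",
    "interpolate_alignment",
    "align",
    "write_alignment_tsv",
]

PROB_FLOOR = 1e-12  # probabilities are floored here before taking logs


class InfeasibleAlignmentError(RuntimeError):
    """No feasible strictly-increasing path exists for these inputs."""


@dataclasses.dataclass(frozen=True)
class AlignmentConfig:
    """Alignment hyper-parameters.

    omega
        Weight of the kinetic prior against accumulated similarity, in [0,1].
    k_ms
        Minimum backward search window in ms.
    calcium_downsample_ms
        Template decimation bin width L_C (ms per sample after decimation).
    dna_downsample
        DNA bin size L_D (nucleotides per alignment row in binned mode).
    extend_search_window
        When true (default) the backward window is widened, if needed, to
        cover the bulk (1 - 1e-4) of the kinetic step prior for an L_D-
        nucleotide step, so binned records are never forcibly compressed.
    """

    omega: float = 0.01
    k_ms: float = 2000.0
    calcium_downsample_ms: float = 50.0
    dna_downsample: int = 100
    extend_search_window: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.omega <= 1:
            raise ValueError("omega must lie in [0, 1]")
        if self.k_ms < self.calcium_downsample_ms:
            raise ValueError("k must be at least one decimated sample period")
        if self.dna_downsample < 1:
            raise ValueError("dna_downsample must be >= 1")


@dataclasses.dataclass
class Alignment:
    """Estimated incorporation times with the path's accumulated score."""

    times_ms: np.ndarray
    log_likelihood: float
    template_id: int | None = None
    sample_indices: np.ndarray | None = None
    backpointers: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=np.float64)


def _quadrature_probs(
    f, values: np.ndarray, noise: tuple[float, float], n_quad: int, floor: float
) -> tuple[np.ndarray, np.ndarray]:
    """Error probabilities f(a*c + s*Z) at Gauss-Hermite nodes of Z.

    Returns the (T, n_quad) probability matrix and the log node weights.
    Marginalizing over Z accounts for the calcium the template cannot
    predict (spike noise through the calcium kernel).
    """
    a, s = noise
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    log_w = np.log(weights / weights.sum())
    p = np.clip(f(a * values[:, None] + s * nodes[None, :]), floor, 1.0 - floor)
    return p, log_w


def build_similarity(
    errors: np.ndarray,
    template: TimeTrace,
    f: ErrorFunction,
    floor: float = PROB_FLOOR,
    noise: tuple[float, float] | None = None,
    n_quad: int = 21,
) -> np.ndarray:
    """Local log-likelihood matrix A[n, t] = ln P(d_n | written at time t).

    Row n is ln f(c*_t) where the strand shows an error and ln(1 - f(c*_t))
    where it does not; probabilities are floored before the log so every
    entry is finite.  When ``noise = (attenuation, scale)`` is given (see
    ``neural.template_noise_stats``) the error probability is first
    marginalized over the spike-driven calcium the template does not
    predict.
    """
    d = np.asarray(errors, dtype=np.float64)
    if len(template) < 1:
        raise ValueError("template must be non-empty")
    if noise is None:
        p = np.clip(f(template.values), floor, 1.0 - floor)
    else:
        pz, log_w = _quadrature_probs(f, template.values, noise, n_quad, floor)
        p = np.clip(pz @ np.exp(log_w), floor, 1.0 - floor)
    log_p = np.log(p)
    log_q = np.log1p(-p)
    return d[:, None] * log_p[None, :] + (1.0 - d)[:, None] * log_q[None, :]


def bin_errors(errors: np.ndarray, dna_downsample: int) -> tuple[np.ndarray, np.ndarray]:
    """Sum errors over consecutive bins of L_D nucleotides.

    Returns ``(counts, sizes)``; the final bin may be smaller than L_D.
    Total error count is conserved.
    """
    if dna_downsample < 1:
        raise ValueError("dna_downsample must be >= 1")
    d = np.asarray(errors)
    n = d.size
    n_bins = int(np.ceil(n / dna_downsample))
    counts = np.zeros(n_bins, dtype=np.int64)
    np.add.at(counts, np.arange(n) // dna_downsample, d.astype(np.int64))
    sizes = np.full(n_bins, dna_downsample, dtype=np.int64)
    sizes[-1] = n - (n_bins - 1) * dna_downsample
    return counts, sizes


def build_binned_similarity(
    bin_counts: np.ndarray,
    template: TimeTrace,
    f: ErrorFunction,
    bin_sizes: np.ndarray,
    floor: float = PROB_FLOOR,
    noise: tuple[float, float] | None = None,
    n_quad: int = 21,
) -> np.ndarray:
    """Binomial local log-likelihoods for binned records.

    A[n', t'] = ln Binomial(size_n', f(c_t')) pmf at count d'_n'.  With all
    bin sizes 1 this reduces exactly to :func:`build_similarity`.

    When ``noise`` is given the binomial is mixed over the unpredicted
    calcium, treated as *shared* within a bin: the nucleotides of one bin
    were written close together in time, so they see correlated calcium
    noise, which over-disperses the counts relative to a plain binomial.
    """
    d = np.asarray(bin_counts, dtype=np.float64)
    L = np.asarray(bin_sizes, dtype=np.float64)
    if np.any(d < 0) or np.any(d > L):
        raise ValueError("bin error count outside [0, bin size]")
    log_choose = gammaln(L + 1.0) - gammaln(d + 1.0) - gammaln(L - d + 1.0)
    if noise is None:
        p = np.clip(f(template.values), floor, 1.0 - floor)
        log_p = np.log(p)
        log_q = np.log1p(-p)
        return (
            log_choose[:, None]
            + d[:, None] * log_p[None, :]
            + (L - d)[:, None] * log_q[None, :]
        )
    pz, log_w = _quadrature_probs(f, template.values, noise, n_quad, floor)
    log_pz = np.log(pz)  # (T, n_quad)
    log_qz = np.log1p(-pz)
    A = np.empty((d.size, len(template)))
    for i in range(d.size):
        A[i] = log_choose[i] + logsumexp(
            d[i] * log_pz + (L[i] - d[i]) * log_qz + log_w, axis=1
        )
    return A


def decimate_template(template: TimeTrace, calcium_downsample_ms: float) -> TimeTrace:
    """Block-average the template into bins of width L_C.

    Timestamps move to block midpoints; a trailing partial block is dropped.
    L_C must be an integer multiple of the template sample period.
    """
    period = template.sample_period_ms
    factor_f = calcium_downsample_ms / period
    factor = int(round(factor_f))
    if factor < 1 or abs(factor - factor_f) > 1e-9:
        raise ValueError("calcium_downsample_ms must be a multiple of the sample period")
    if factor == 1:
        return template
    n_blocks = len(template) // factor
    if n_blocks < 1:
        raise ValueError("template shorter than one decimation block")
    v = template.values[: n_blocks * factor].reshape(n_blocks, factor).mean(axis=1)
    t0 = template.t0_ms + (factor - 1) * period / 2.0
    return TimeTrace(v, calcium_downsample_ms, t0)


def _accumulate_vectorized(A, log_pmf, omega, init_log_prior):
    n_rows, n_cols = A.shape
    J = log_pmf.size
    S = np.empty_like(A)
    bp = np.full(A.shape, -1, dtype=np.int64)
    S[0] = A[0] if init_log_prior is None else A[0] + init_log_prior
    if n_rows == 1:
        return S, bp
    w_prior = np.where(np.isneginf(log_pmf), -np.inf, omega * log_pmf)
    w_prior_rev = w_prior[::-1]  # window col i <-> lag J - i
    keep = 1.0 - omega
    pad = np.full(J, -np.inf)
    chunk = 8192
    for n in range(1, n_rows):
        scaled = keep * S[n - 1]
        scaled[np.isneginf(S[n - 1])] = -np.inf  # keep infeasibility even at omega=1
        prev = np.concatenate([pad, scaled])
        win = sliding_window_view(prev, J)[:n_cols]  # win[t, i] = keep*S[n-1, t-J+i]
        for lo in range(0, n_cols, chunk):
            hi = min(lo + chunk, n_cols)
            total = win[lo:hi] + w_prior_rev
            rev = total[:, ::-1]  # rev col a <-> lag a + 1
            a = np.argmax(rev, axis=1)  # first max = smallest lag on ties
            best = np.take_along_axis(rev, a[:, None], axis=1)[:, 0]
            S[n, lo:hi] = A[n, lo:hi] + best
            t_idx = np.arange(lo, hi)
            bp[n, lo:hi] = t_idx - (a + 1)
            infeasible = ~np.isfinite(best)
            S[n, lo:hi][infeasible] = -np.inf
            bp[n, lo:hi][infeasible] = -1
    return S, bp


def _accumulate_looped(A, log_pmf, omega, init_log_prior):
    """Reference engine: plain sequential loops over (row, cell, lag).

    Returns the scores, backpointers, and the number of lag evaluations
    performed (for complexity checks).  Must agree with the vectorized
    engine to floating round-off.
    """
    n_rows, n_cols = A.shape
    J = log_pmf.size
    S = np.empty_like(A)
    bp = np.full(A.shape, -1, dtype=np.int64)
    S[0] = A[0] if init_log_prior is None else A[0] + init_log_prior
    keep = 1.0 - omega
    n_ops = 0
    for n in range(1, n_rows):
        for t in range(n_cols):
            best = -np.inf
            best_src = -1
            for j in range(1, min(J, t) + 1):
                n_ops += 1
                prev = S[n - 1, t - j]
                if prev == -np.inf or log_pmf[j - 1] == -np.inf:
                    continue
                cand = keep * prev + omega * log_pmf[j - 1]
                if cand > best:  # strict: first (smallest) lag wins ties
                    best = cand
                    best_src = t - j
            if np.isfinite(best):
                S[n, t] = A[n, t] + best
                bp[n, t] = best_src
            else:
                S[n, t] = -np.inf
                bp[n, t] = -1
    return S, bp, n_ops


def accumulate(
    A: np.ndarray,
    prior: LagPrior,
    omega: float,
    init_log_prior: np.ndarray | None = None,
    engine: str = "vectorized",
) -> tuple[np.ndarray, np.ndarray]:
    """Run the forward DP, returning accumulated scores and backpointers.

    ``A`` is the (rows x template samples) local similarity matrix, ``prior``
    the kinetic lag prior, ``omega`` the prior weight.  ``init_log_prior``
    optionally adds a start-time log-prior to the first row (exposed as a
    hook; the default analyses leave it unset).  Cells that no feasible
    predecessor can reach score -inf.  Backpointer entries are predecessor
    column indices (-1 where undefined).
    """
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2:
        raise ValueError("similarity matrix must be 2-D")
    n_rows, n_cols = A.shape
    if n_cols < n_rows:
        raise InfeasibleAlignmentError(
            f"cannot place {n_rows} ordered elements in {n_cols} time slots"
        )
    if engine == "vectorized":
        return _accumulate_vectorized(A, prior.log_pmf, omega, init_log_prior)
    if engine == "looped":
        S, bp, _ = _accumulate_looped(A, prior.log_pmf, omega, init_log_prior)
        return S, bp
    raise ValueError(f"unknown engine {engine!r}")


def traceback(
    S: np.ndarray,
    bp: np.ndarray,
    *,
    sample_period_ms: float = 1.0,
    t0_ms: float = 0.0,
    keep_backpointers: bool = False,
) -> Alignment:
    """Recover the maximum-likelihood path from scores and backpointers.

    The path ends at the most likely final time (earliest column on ties)
    and follows backpointers to the first row.  Returned times are in ms on
    the template clock.
    """
    n_rows = S.shape[0]
    last = S[n_rows - 1]
    t = int(np.argmax(last))  # argmax returns the earliest maximizer
    if not np.isfinite(last[t]):
        raise InfeasibleAlignmentError("no feasible path: final row is all -inf")
    idx = np.empty(n_rows, dtype=np.int64)
    idx[-1] = t
    for n in range(n_rows - 1, 0, -1):
        t = int(bp[n, t])
        if t < 0:
            raise InfeasibleAlignmentError("broken backpointer chain")
        idx[n - 1] = t
    return Alignment(
        times_ms=t0_ms + idx * sample_period_ms,
        log_likelihood=float(last[idx[-1]]),
        sample_indices=idx,
        backpointers=bp if keep_backpointers else None,
    )


def interpolate_alignment(
    bin_alignment: Alignment,
    dna_downsample: int,
    n_nucleotides: int,
    *,
    min_separation_ms: float | None = None,
    sample_period_ms: float | None = None,
) -> Alignment:
    """Expand a bin-level alignment to per-nucleotide times.

    Bin times are anchored at bin-midpoint nucleotide indices and linearly
    interpolated (with linear extrapolation beyond the first and last
    anchors).  Strict increase is enforced with a minimum separation of one
    template-sample period shared across the L_D nucleotides of a bin
    (i.e. period / L_D per nucleotide), which reduces to the full-resolution
    rule when L_D = 1.
    """
    L = dna_downsample
    t_bins = bin_alignment.times_ms
    n_bins = t_bins.size
    if n_bins != int(np.ceil(n_nucleotides / L)):
        raise ValueError("bin alignment does not cover the requested strand")
    if min_separation_ms is None:
        if sample_period_ms is None:
            raise ValueError("need min_separation_ms or sample_period_ms")
        min_separation_ms = sample_period_ms / L
    if L == 1:
        return Alignment(
            t_bins.copy(), bin_alignment.log_likelihood, bin_alignment.template_id
        )
    starts = np.arange(n_bins) * L
    ends = np.minimum(starts + L, n_nucleotides)
    anchors = (starts + ends - 1) / 2.0
    x = np.arange(n_nucleotides, dtype=np.float64)
    if n_bins == 1:
        times = np.full(n_nucleotides, float(t_bins[0]))
    else:
        times = np.interp(x, anchors, t_bins)
        # linear extrapolation past the end anchors using the edge slopes
        s0 = (t_bins[1] - t_bins[0]) / (anchors[1] - anchors[0])
        s1 = (t_bins[-1] - t_bins[-2]) / (anchors[-1] - anchors[-2])
        left = x < anchors[0]
        right = x > anchors[-1]
        times[left] = t_bins[0] + (x[left] - anchors[0]) * s0
        times[right] = t_bins[-1] + (x[right] - anchors[-1]) * s1
    # enforce strict increase: shift into a frame where the floor is flat
    delta = min_separation_ms
    u = np.maximum.accumulate(times - x * delta)
    times = u + x * delta
    return Alignment(times, bin_alignment.log_likelihood, bin_alignment.template_id)


def align(
    errors: np.ndarray,
    template: TimeTrace,
    f: ErrorFunction,
    kin: KineticModel,
    config: AlignmentConfig,
    mode: str = "binned",
    init_log_prior: np.ndarray | None = None,
    template_id: int | None = None,
    engine: str = "vectorized",
    template_noise: tuple[float, float] | None = None,
) -> Alignment:
    """End-to-end alignment of an error strand to a calcium template.

    ``mode="binned"`` (the production path) decimates the template to L_C,
    bins the strand into L_D-nucleotide rows with binomial likelihoods,
    aligns with the L_D-step kinetic prior, and interpolates back to
    per-nucleotide times.  ``mode="full"`` aligns nucleotide-by-nucleotide
    on the template's native clock.  ``template_noise`` optionally carries
    the (attenuation, scale) statistics of the calcium the template cannot
    predict (see ``neural.template_noise_stats``); when given, the local
    likelihoods marginalize over it.  Deterministic given its inputs.
    """
    errors = np.asarray(errors)
    n = errors.size
    if n < 1:
        raise ValueError("empty error strand")
    if mode == "full":
        dec = template
        A = build_similarity(errors, dec, f, noise=template_noise)
        prior = step_log_pmf(
            kin,
            dec.sample_period_ms,
            config.k_ms,
            n_steps=1,
            extend=config.extend_search_window,
        )
        S, bp = accumulate(A, prior, config.omega, init_log_prior, engine=engine)
        aln = traceback(S, bp, sample_period_ms=dec.sample_period_ms, t0_ms=dec.t0_ms)
        aln.template_id = template_id
        return aln
    if mode != "binned":
        raise ValueError(f"unknown mode {mode!r}")
    dec = decimate_template(template, config.calcium_downsample_ms)
    counts, sizes = bin_errors(errors, config.dna_downsample)
    A = build_binned_similarity(counts, dec, f, sizes, noise=template_noise)
    prior = step_log_pmf(
        kin,
        dec.sample_period_ms,
        config.k_ms,
        n_steps=config.dna_downsample,
        extend=config.extend_search_window,
    )
    S, bp = accumulate(A, prior, config.omega, init_log_prior, engine=engine)
    bin_aln = traceback(S, bp, sample_period_ms=dec.sample_period_ms, t0_ms=dec.t0_ms)
    aln = interpolate_alignment(
        bin_aln,
        config.dna_downsample,
        n,
        sample_period_ms=dec.sample_period_ms,
    )
    aln.template_id = template_id
    return aln


def write_alignment_tsv(path, aln: Alignment, true_times_ms=None) -> None:
    """Alignment output TSV: (nucleotide_index, estimated_time_ms[, true_time_ms])."""
    import pandas as pd

    cols = {
        "nucleotide_index": np.arange(aln.times_ms.size),
        "estimated_time_ms": aln.times_ms,
    }
    if true_times_ms is not None:
        cols["true_time_ms"] = np.asarray(true_times_ms, dtype=np.float64)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
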