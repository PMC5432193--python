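"""DNA-polymerase physics: the error transfer function and kinetic model.

A molecular-recorder DNAP carries two tunable pieces of physics.

* An *error transfer function* ``f(c)`` mapping local calcium concentration
  to the probability of misincorporating the next nucleotide.  We model it
  as a three-parameter sigmoid

      f(c) = r_max / (1 + exp(b * (c - c0)))

  where ``r_max`` is the ceiling error rate, ``c0`` the concentration at
  half-maximum, and ``b`` the steepness.  Note the sign convention: as
  written the curve *decreases* with calcium when ``b > 0``; recorders whose
  error rate rises with calcium use ``b < 0``.

* A *kinetic model* for the interval ``U`` between successive nucleotide
  incorporations: with probability ``p_pause`` the polymerase pauses and the
  interval is exponential with mean ``pause_mean_ms``; otherwise it extends
  normally and the interval is Gamma(shape, scale).  The mixture mean sets
  the effective incorporation rate, and the pause component dominates the
  distribution's tail.

The kinetic model also supplies the *lag prior* used by the aligner: the
discretized distribution of the time the polymerase needs to advance by a
fixed number of nucleotides, truncated to a backward search window.
"""

from __future__ import annotations

import dataclasses
import functools
import math

import numpy as np
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "ErrorFunction",
    "KineticModel",
    "LagPrior",
    "error_rate",
    "error_rate_inverse",
    "expected_interval",
    "paused_fraction",
    "sample_intervals",
    "lag_log_pmf",
    "step_log_pmf",
]


@dataclasses.dataclass(frozen=True)
class ErrorFunction:
    """Sigmoid calcium-to-error-rate transfer function.

    Attributes
    ----------
    r_max : float
        Maximum error rate, in (0, 1].
    b : float
        Steepness (1 / calcium unit).  Positive b gives a curve that
        decreases with calcium; use negative b for a rising response.
    c0 : float
        Calcium concentration at half-maximum error rate.
    """

    r_max: float
    b: float
    c0: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.r_max <= 1:
            raise ValueError("r_max must lie in (0, 1]")

    def __call__(self, c):
        return error_rate(self, c)

    def inverse(self, r):
        return error_rate_inverse(self, r)


def error_rate(f: ErrorFunction, c):
    """Per-nucleotide error probability at calcium concentration ``c``.

    Vectorizes elementwise; output is strictly inside (0, r_max).
    """
    c = np.asarray(c, dtype=np.float64)
    # clip the exponent to keep the tails finite without changing the result
    z = np.clip(f.b * (c - f.c0), -700.0, 700.0)
    out = f.r_max / (1.0 + np.exp(z))
    return out if out.ndim else float(out)


def error_rate_inverse(f: ErrorFunction, r):
    """The unique concentration ``c`` with ``error_rate(f, c) = r``.

    Requires ``0 < r < r_max``; outside that band the sigmoid is not
    invertible and a ``ValueError`` is raised.
    """
    r = np.asarray(r, dtype=np.float64)
    if np.any(r <= 0) or np.any(r >= f.r_max):
        raise ValueError("error rate outside the invertible band (0, r_max)")
    out = f.c0 + np.log(f.r_max / r - 1.0) / f.b
    return out if out.ndim else float(out)


@dataclasses.dataclass(frozen=True)
class KineticModel:
    """Pause/extension mixture for inter-incorporation intervals.

    ``U ~ p_pause * Exp(pause_mean_ms) + (1 - p_pause) * Gamma(shape, scale)``.

    ``lag_resolution_ms`` records the finest lag grid the model is meant to
    be discretized on; lag priors are tabulated on the (coarser) template
    sample period via exact distribution functions, so this acts as
    metadata rather than a computational knob.
    """

    p_pause: float
    pause_mean_ms: float
    gamma_shape: float
    gamma_scale_ms: float
    lag_resolution_ms: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.p_pause <= 1:
            raise ValueError("p_pause must lie in [0, 1]")
        for name in ("pause_mean_ms", "gamma_shape", "gamma_scale_ms", "lag_resolution_ms"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def interval_cdf(self, x):
        """CDF of the mixture interval U at ``x`` (ms)."""
        x = np.asarray(x, dtype=np.float64)
        pause = stats.expon.cdf(x, scale=self.pause_mean_ms)
        ext = stats.gamma.cdf(x, a=self.gamma_shape, scale=self.gamma_scale_ms)
        return self.p_pause * pause + (1.0 - self.p_pause) * ext


@dataclasses.dataclass(frozen=True)
class LagPrior:
    """Discretized log-pmf over backward lags {1..J} in template-sample units.

    ``log_pmf[j-1]`` is the log-probability that one alignment step spans
    ``j`` template samples; ``k_ms`` is the span of the window (J samples of
    ``sample_period_ms`` each).
    """

    log_pmf: np.ndarray
    k_ms: float
    sample_period_ms: float

    def __post_init__(self) -> None:
        lp = np.asarray(self.log_pmf, dtype=np.float64)
        object.__setattr__(self, "log_pmf", lp)
        total = np.exp(lp).sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError("lag prior must be normalized")

    def __len__(self) -> int:
        return self.log_pmf.size


def expected_interval(kin: KineticModel) -> float:
    """Mean inter-incorporation interval in ms (analytic mixture mean)."""
    return kin.p_pause * kin.pause_mean_ms + (
        1.0 - kin.p_pause
    ) * kin.gamma_shape * kin.gamma_scale_ms


def paused_fraction(kin: KineticModel) -> float:
    """Expected fraction of recording time spent inside pause intervals.

    The pause component contributes ``p_pause * pause_mean`` of every mean
    interval, so the long-run paused-time proportion is that mass over the
    mixture mean.
    """
    mean = expected_interval(kin)
    if not mean > 0:
        raise ValueError("expected interval must be positive")
    return kin.p_pause * kin.pause_mean_ms / mean


def _interval_moments(kin: KineticModel) -> tuple[float, float]:
    """Mean and variance of the single-interval mixture (ms, ms^2)."""
    m1 = expected_interval(kin)
    # second moments: Exp -> 2*mean^2, Gamma -> shape*(shape+1)*scale^2
    m2 = kin.p_pause * 2.0 * kin.pause_mean_ms**2 + (1.0 - kin.p_pause) * (
        kin.gamma_shape * (kin.gamma_shape + 1.0) * kin.gamma_scale_ms**2
    )
    return m1, m2 - m1 * m1


def sample_intervals(kin: KineticModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. intervals U from the continuous mixture (ms)."""
    is_pause = rng.random(n) < kin.p_pause
    out = rng.gamma(kin.gamma_shape, kin.gamma_scale_ms, size=n)
    n_pause = int(is_pause.sum())
    if n_pause:
        out[is_pause] = rng.exponential(kin.pause_mean_ms, size=n_pause)
    return out


def lag_log_pmf(kin: KineticModel, sample_period_ms: float, k_ms: float) -> LagPrior:
    """Discretize the single-interval mixture onto lag bins of one sample.

    Bin ``j`` (lags are 1-based; lag 0 is excluded so consecutive
    incorporations always advance in time) integrates the mixture density
    over ``((j-1)*period, j*period]``.  The pmf is truncated at ``k_ms`` and
    renormalized.
    """
    if k_ms < sample_period_ms:
        raise ValueError("search window k must be at least one sample period")
    n_bins = int(round(k_ms / sample_period_ms))
    if abs(n_bins * sample_period_ms - k_ms) > 1e-9 * max(1.0, k_ms):
        raise ValueError("sample period must divide k")
    edges = np.arange(n_bins + 1) * sample_period_ms
    mass = np.diff(kin.interval_cdf(edges))
    total = mass.sum()
    if not total > 0:
        raise ValueError("no interval mass inside the search window")
    mass = np.clip(mass / total, 1e-300, None)
    return LagPrior(np.log(mass), n_bins * sample_period_ms, sample_period_ms)


def _log_bin_mass(dist, edges: np.ndarray) -> np.ndarray:
    """Log-mass of a scipy frozen distribution on consecutive bins.

    Uses CDF differences where they are representable and falls back to the
    midpoint log-density (times bin width) where the mass underflows, so the
    deep tails keep their correct order of magnitude in log space.
    """
    cdf_mass = np.diff(dist.cdf(edges))
    with np.errstate(divide="ignore"):
        log_cdf = np.log(np.clip(cdf_mass, 0.0, None))
    mid = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pdf = dist.logpdf(mid) + np.log(widths)
    log_pdf = np.where(np.isnan(log_pdf), -np.inf, log_pdf)
    return np.maximum(log_cdf, log_pdf)


def _single_step_log_mass(kin: KineticModel, edges: np.ndarray) -> np.ndarray:
    """Exact-tail log bin masses for the single-interval mixture."""
    parts = []
    if kin.p_pause > 0:
        parts.append(
            math.log(kin.p_pause)
            + _log_bin_mass(stats.expon(scale=kin.pause_mean_ms), edges)
        )
    if kin.p_pause < 1:
        parts.append(
            math.log(1.0 - kin.p_pause)
            + _log_bin_mass(
                stats.gamma(a=kin.gamma_shape, scale=kin.gamma_scale_ms), edges
            )
        )
    return logsumexp(np.vstack(parts), axis=0) if len(parts) > 1 else parts[0]


def _multi_step_log_mass(
    kin: KineticModel, n_steps: int, edges: np.ndarray
) -> np.ndarray:
    """Log bin masses for the sum of ``n_steps`` i.i.d. mixture intervals.

    Conditions on the number of pauses m ~ Binomial(n_steps, p_pause): the
    extension part sums to Gamma((n-m)*shape, scale) and the pause part to
    Gamma(m, pause_mean); the two are convolved on the lag grid in log
    space, and the m-components are combined with exact binomial
    log-weights.  Working in log space keeps the far tails finite and
    correctly ordered, which matters because they act as soft kinetic
    barriers during alignment.
    """
    n_bins = edges.size - 1
    log_w = stats.binom.logpmf(np.arange(n_steps + 1), n_steps, kin.p_pause)
    components = []
    weights = []
    for m in range(n_steps + 1):
        if log_w[m] < -60.0:  # negligible in the logsumexp
            continue
        n_ext = n_steps - m
        if n_ext == 0:
            comp = _log_bin_mass(stats.gamma(a=m, scale=kin.pause_mean_ms), edges)
        elif m == 0:
            comp = _log_bin_mass(
                stats.gamma(a=n_ext * kin.gamma_shape, scale=kin.gamma_scale_ms), edges
            )
        else:
            ext = _log_bin_mass(
                stats.gamma(a=n_ext * kin.gamma_shape, scale=kin.gamma_scale_ms), edges
            )
            pause = _log_bin_mass(stats.gamma(a=m, scale=kin.pause_mean_ms), edges)
            comp = np.full(n_bins, -np.inf)
            for j in range(n_bins):
                # sum lands in bin j when the parts' bins are i and j-1-i
                terms = ext[: j + 1] + pause[j::-1]
                comp[j] = logsumexp(terms)
        components.append(comp)
        weights.append(log_w[m])
    stacked = np.vstack(components) + np.asarray(weights)[:, None]
    return logsumexp(stacked, axis=0)


@functools.lru_cache(maxsize=64)
def _step_log_pmf_cached(
    kin: KineticModel,
    sample_period_ms: float,
    k_ms: float,
    n_steps: int,
    extend: bool,
    band_lo: float,
    band_hi: float,
) -> LagPrior:
    m1, var = _interval_moments(kin)
    support = n_steps * m1 + 12.0 * math.sqrt(max(n_steps * var, 1.0)) + 10.0 * (
        kin.pause_mean_ms if kin.p_pause > 0 else 0.0
    )
    support = max(support, k_ms + sample_period_ms)
    n_bins = int(math.ceil(support / sample_period_ms))
    edges = np.arange(n_bins + 1) * sample_period_ms

    if n_steps == 1:
        log_mass = _single_step_log_mass(kin, edges)
    else:
        log_mass = _multi_step_log_mass(kin, n_steps, edges)

    j_min = max(1, int(round(k_ms / sample_period_ms)))
    lo = 0
    if extend:
        prob = np.exp(log_mass - logsumexp(log_mass))
        cum = np.cumsum(prob)
        # the outer window covers at least the configured k and at least the
        # typical step (upper quartile of the step distribution)
        q75 = int(np.searchsorted(cum, 0.75)) + 1
        cap = min(n_bins, max(j_min, q75))
        if n_steps > 1:
            # kinetic band: a multi-nucleotide step has both a minimum and a
            # typical maximum duration; restrict the search to the central
            # [band_lo, band_hi] quantiles of the step distribution (within
            # the outer window) so the DP cannot wander off the record
            lo = min(int(np.searchsorted(cum, band_lo)), cap - 2)
            n_keep = int(np.clip(np.searchsorted(cum, band_hi) + 1, lo + 2, cap))
        else:
            n_keep = cap
    else:
        n_keep = min(n_bins, j_min)
    kept = log_mass[:n_keep].copy()
    if lo > 0:
        kept[:lo] = -np.inf
    finite = np.isfinite(kept)
    if not finite.any():
        raise ValueError("no step mass inside the search window")
    kept = kept - logsumexp(kept[finite])
    return LagPrior(kept, n_keep * sample_period_ms, sample_period_ms)


def step_log_pmf(
    kin: KineticModel,
    sample_period_ms: float,
    k_ms: float,
    n_steps: int = 1,
    *,
    extend: bool = True,
    band_lo: float = 0.05,
    band_hi: float = 0.95,
) -> LagPrior:
    """Lag prior for an alignment step spanning ``n_steps`` incorporations.

    For binned alignments each dynamic-programming step advances one DNA bin,
    i.e. ``n_steps = L_D`` nucleotide incorporations, so the kinetically
    correct step prior is the L_D-fold convolution of the single-interval
    distribution, computed here in log space (exact binomial mixture over
    pause counts) so its tails stay finite and correctly ordered.

    When ``extend`` is true (the default) the backward search window for
    multi-nucleotide steps is an Itakura-style kinetic band: lags are
    restricted to the central ``[band_lo, band_hi]`` quantiles of the step
    distribution, inside an outer window that spans at least the configured
    ``k_ms`` and at least the distribution's upper quartile.  A step of L_D
    incorporations has both a kinetic minimum and a typical maximum
    duration; leaving implausible lags searchable lets the alignment wander
    off the record entirely.  Single-nucleotide steps (``n_steps = 1``) keep
    the plain ``[1, k_ms]`` window.  With ``extend=False`` the window is
    exactly ``[1, k_ms]`` in all cases.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not 0 < band_lo < band_hi < 1:
        raise ValueError("need 0 < band_lo < band_hi < 1")
    if n_steps == 1 and not extend:
        return lag_log_pmf(kin, sample_period_ms, k_ms)
    return _step_log_pmf_cached(
        kin,
        float(sample_period_ms),
        float(k_ms),
        int(n_steps),
        bool(extend),
        float(band_lo),
        float(band_hi),
    )
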