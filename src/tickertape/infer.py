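"""Inference from aligned records: template selection, timing accuracy,
and neural-parameter estimation.

Once a record is aligned, its error indicators acquire timestamps and can
be treated as a (noisy, thresholded) readout of calcium.  This module
covers the downstream questions: which tuning template generated the
record (maximum-likelihood selection over an ensemble), how accurate the
timing estimate is (RMSD), how strongly the neuron was tuned (slope of the
calcium-tuning curve recovered through the inverse error sigmoid), and
which direction it preferred (GLMs on errors and spikes).  Also here: the
population filters used to restrict analyses to active, well-modelled
neurons, patch-shuffling of an experiment's temporal structure, and
bootstrap confidence intervals.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import statsmodels.api as sm

from .align import Alignment, AlignmentConfig, align
from .dnap import ErrorFunction, KineticModel, error_rate_inverse
from .neural import SpikeTrain, TuningModel
from .traces import TimeTrace

__all__ = [
    "TemplateEnsemble",
    "TuningEstimate",
    "select_template",
    "timing_rmsd",
    "estimate_slope",
    "calcium_covariate_slope",
    "estimate_preferred_direction",
    "ground_truth_pd",
    "population_filter",
    "shuffle_patches",
    "bootstrap_ci",
    "circular_error",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class TemplateEnsemble:
    """Candidate tunings with their expected-calcium templates C-dagger_m.

    ``noise_stats`` optionally holds per-template (attenuation, scale)
    statistics (``neural.template_noise_stats``) used to marginalize the
    alignment likelihood over spike-driven calcium noise.
    """

    tunings: list[TuningModel]
    templates: list[TimeTrace]
    noise_stats: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if len(self.tunings) != len(self.templates):
            raise ValueError("one template per tuning required")
        if not self.templates:
            raise ValueError("ensemble must be non-empty")
        if self.noise_stats is not None and len(self.noise_stats) != len(self.templates):
            raise ValueError("one noise statistic per template required")
        n0, p0 = len(self.templates[0]), self.templates[0].sample_period_ms
        for t in self.templates[1:]:
            if len(t) != n0 or t.sample_period_ms != p0:
                raise ValueError("all templates must share clock and length")

    def __len__(self) -> int:
        return len(self.templates)


@dataclasses.dataclass
class TuningEstimate:
    """Summary of one aligned record's inferred tuning."""

    slope_ratio: float | None = None
    theta_star: float | None = None
    pseudo_r2: float | None = None
    rmsd_s: float | None = None

    def __post_init__(self) -> None:
        if self.theta_star is not None:
            self.theta_star = float(self.theta_star) % (2 * math.pi)


def select_template(
    errors: np.ndarray,
    ensemble: TemplateEnsemble,
    f: ErrorFunction,
    kin: KineticModel,
    config: AlignmentConfig,
    mode: str = "binned",
) -> tuple[int, Alignment]:
    """Align the strand to every template; keep the most likely alignment.

    The intuition: the record should most closely resemble the signal that
    generated it.  Ties break toward the lowest template id.
    """
    best_id, best = -1, None
    for m, template in enumerate(ensemble.templates):
        noise = None if ensemble.noise_stats is None else ensemble.noise_stats[m]
        aln = align(
            errors, template, f, kin, config, mode=mode, template_id=m,
            template_noise=noise,
        )
        if best is None or aln.log_likelihood > best.log_likelihood:
            best_id, best = m, aln
    return best_id, best


def timing_rmsd(true_times, est_times, variant: str = "standard") -> float:
    """Root-mean-square deviation between true and estimated times.

    ``standard`` is sqrt(mean((tau - tau*)^2)); ``as_printed`` is the
    sqrt(sum)/N variant some reports use.  Units follow the inputs
    (conventionally seconds).
    """
    t = np.asarray(true_times, dtype=np.float64)
    e = np.asarray(est_times, dtype=np.float64)
    if t.size != e.size:
        raise ValueError("time vectors must have equal length")
    sq = np.square(t - e)
    if variant == "standard":
        return float(np.sqrt(sq.mean()))
    if variant == "as_printed":
        return float(np.sqrt(sq.sum()) / t.size)
    raise ValueError(f"unknown variant {variant!r}")


def calcium_covariate_slope(calcium: TimeTrace, covariate: TimeTrace) -> float:
    """Least-squares slope of a calcium trace against a covariate trace.

    Used to compute the ground-truth effective relationship between
    (standardized) calcium and the stimulus, m_ca.
    """
    if len(calcium) != len(covariate):
        raise ValueError("calcium and covariate must share a clock")
    slope, _ = np.polyfit(covariate.values, calcium.values, 1)
    return float(slope)


def estimate_slope(
    errors: np.ndarray,
    est_times_ms: np.ndarray,
    covariate: TimeTrace,
    f: ErrorFunction,
    true_calcium: TimeTrace,
    n_bins: int = 20,
) -> float:
    """Tuning-strength recovery: the ratio m*_ca / m_ca.

    Error indicators are grouped into ``n_bins`` equal-count bins by the
    covariate value at their estimated incorporation times; each bin's mean
    error rate is pushed through the inverse error sigmoid to an inferred
    calcium level, and the least-squares slope of inferred calcium against
    covariate gives m*_ca.  The denominator m_ca is the slope of the
    ground-truth calcium trace against the covariate.  Bin rates outside
    the invertible band are clipped inward with a logged warning.
    """
    d = np.asarray(errors, dtype=np.float64)
    x = covariate.value_at(np.asarray(est_times_ms, dtype=np.float64), clip=True)
    order = np.argsort(x, kind="stable")
    groups = np.array_split(order, n_bins)
    rates, levels = [], []
    for g in groups:
        if g.size == 0:
            continue
        rates.append(d[g].mean())
        levels.append(x[g].mean())
    rates = np.asarray(rates)
    lo, hi = f.r_max * 1e-6, f.r_max * (1.0 - 1e-6)
    if np.any(rates >= f.r_max) or np.any(rates <= 0):
        logger.warning("bin error rate outside (0, r_max); clipping before inversion")
    rates = np.clip(rates, lo, hi)
    inferred_ca = error_rate_inverse(f, rates)
    m_star, _ = np.polyfit(np.asarray(levels), inferred_ca, 1)
    m_true = calcium_covariate_slope(true_calcium, covariate)
    return float(m_star / m_true)


def _fit_glm(y, X, family):
    model = sm.GLM(y, X, family=family)
    return model.fit()


def estimate_preferred_direction(
    errors: np.ndarray,
    est_times_ms: np.ndarray,
    vx: TimeTrace,
    vy: TimeTrace,
) -> tuple[float, np.ndarray]:
    """Preferred direction from an aligned record.

    Fits a logistic GLM of the per-nucleotide error indicator on the x/y
    hand-velocity components sampled at the estimated incorporation times;
    theta* is the angle of the fitted velocity coefficient vector.
    """
    t = np.asarray(est_times_ms, dtype=np.float64)
    X = np.column_stack([vx.value_at(t, clip=True), vy.value_at(t, clip=True)])
    if np.any(X.std(axis=0) == 0):
        raise ValueError("degenerate design: a velocity component has zero variance")
    X = sm.add_constant(X)
    res = _fit_glm(np.asarray(errors, dtype=np.float64), X, sm.families.Binomial())
    beta = res.params
    theta = math.atan2(beta[2], beta[1]) % (2 * math.pi)
    return theta, np.asarray(beta)


def ground_truth_pd(
    spikes: SpikeTrain, vx: TimeTrace, vy: TimeTrace
) -> tuple[float, float]:
    """Ground-truth preferred direction from the neural data itself.

    Poisson GLM of 1 ms-binned spike counts on the velocity components;
    returns (theta, McFadden pseudo-R^2), where pseudo-R^2 is
    1 - ll_model / ll_null against an intercept-only fit.
    """
    y = spikes.spikes.astype(np.float64)
    if y.size != len(vx) or y.size != len(vy):
        raise ValueError("spikes and kinematics must share a clock")
    X = np.column_stack([vx.values, vy.values])
    if np.any(X.std(axis=0) == 0):
        raise ValueError("degenerate design: a velocity component has zero variance")
    res = _fit_glm(y, sm.add_constant(X), sm.families.Poisson())
    null = _fit_glm(y, np.ones((y.size, 1)), sm.families.Poisson())
    theta = math.atan2(res.params[2], res.params[1]) % (2 * math.pi)
    pr2 = 1.0 - res.llf / null.llf
    return theta, float(pr2)


def population_filter(
    estimates, min_rate_hz: float = 20.0, min_pseudo_r2: float = 0.05
):
    """Keep neurons with mean rate > min_rate and pseudo-R^2 > min_pseudo_r2.

    ``estimates`` is a sequence of mappings (or objects) exposing
    ``mean_rate_hz`` and ``pseudo_r2``.
    """

    def _get(e, key):
        return e[key] if isinstance(e, dict) else getattr(e, key)

    return [
        e
        for e in estimates
        if _get(e, "mean_rate_hz") > min_rate_hz and _get(e, "pseudo_r2") > min_pseudo_r2
    ]


def shuffle_patches(streams, patch_len_ms: float, seed=0):
    """Jointly permute fixed-length temporal patches of several streams.

    All streams (TimeTrace or SpikeTrain) must share a clock.  The streams
    are cut into aligned patches of ``patch_len_ms``, one shared random
    permutation is applied, and a trailing partial patch stays in place, so
    kinematics and spikes remain mutually aligned while the experiment's
    temporal structure is destroyed.
    """
    if not streams:
        return []
    period = streams[0].sample_period_ms
    n = len(streams[0])
    for s in streams:
        if s.sample_period_ms != period or len(s) != n:
            raise ValueError("all streams must share a clock")
    per_patch = int(round(patch_len_ms / period))
    if per_patch < 1:
        raise ValueError("patch length shorter than one sample")
    n_full = n // per_patch
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n_full)
    idx = np.concatenate(
        [
            (perm[:, None] * per_patch + np.arange(per_patch)).reshape(-1),
            np.arange(n_full * per_patch, n),
        ]
    ).astype(np.int64)
    out = []
    for s in streams:
        if isinstance(s, SpikeTrain):
            out.append(SpikeTrain(s.spikes[idx], s.sample_period_ms))
        else:
            out.append(TimeTrace(s.values[idx], s.sample_period_ms, s.t0_ms))
    return out


def bootstrap_ci(
    values,
    level: float = 0.95,
    n_boot: int = 2000,
    seed=0,
    stat: str = "mean",
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean (or median) of a sample."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("need at least two values to bootstrap")
    fn = np.mean if stat == "mean" else np.median
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.integers(0, v.size, size=(n_boot, v.size))
    stats = fn(v[draws], axis=1)
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(stats, alpha)), float(np.quantile(stats, 1.0 - alpha))


def circular_error(theta_a: float, theta_b: float) -> float:
    """Absolute angular difference wrapped to [0, pi]."""
    d = abs((theta_a - theta_b) % (2 * math.pi))
    return min(d, 2 * math.pi - d)
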