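"""Stimuli, kinematics, tuning models, spikes, and calcium.

This module generates everything upstream of the recorder: experimental
covariates (block stimuli or synthetic center-out reach kinematics), firing
rates from a tuning model, Bernoulli spikes at 1 ms, spike-driven calcium
transients, and the expected-calcium *templates* the aligner searches
against.

Conventions: the simulation clock is 1 ms; rate traces are expressed as
spike probability per 1 ms bin; calcium uses an unnormalized exponential
kernel (an isolated spike decays from a peak of 1 with time constant tau).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Union

import numpy as np
from scipy import signal

from .traces import TimeTrace

__all__ = [
    "LinearTuning",
    "CosineTuning",
    "TuningModel",
    "SpikeTrain",
    "SIM_PERIOD_MS",
    "make_block_stimulus",
    "make_center_out_kinematics",
    "speed_gate",
    "rate_from_tuning",
    "sample_spikes",
    "calcium_from_spikes",
    "calcium_template",
    "template_noise_stats",
]

SIM_PERIOD_MS = 1.0


@dataclasses.dataclass(frozen=True)
class LinearTuning:
    """Firing rate linear in a scalar stimulus: lambda_t = m*I_t + lambda_min.

    ``m`` is in spikes/ms per unit stimulus and ``lambda_min`` in spikes/ms,
    so the resulting rate is directly a per-1 ms spike probability.
    """

    m: float = 0.05
    lambda_min: float = 0.0

    kind = "linear"


@dataclasses.dataclass(frozen=True)
class CosineTuning:
    """Speed-scaled cosine direction tuning for a motor cortical neuron.

    Rate (spikes/s) is
    ``lambda_min + (lambda_max - lambda_min) * (v/ref_speed) * (1 + cos(phi - theta))/2``
    where ``phi`` is the instantaneous movement direction and ``v`` the hand
    speed; at the reference speed, movement along the preferred direction
    ``theta`` fires at ``lambda_max`` and anti-parallel movement at
    ``lambda_min``.
    """

    theta: float
    lambda_min_hz: float = 10.0
    lambda_max_hz: float = 150.0
    ref_speed: float = 0.5  # m/s; the default kinematics peak speed

    kind = "cosine"

    def __post_init__(self) -> None:
        if self.lambda_min_hz > self.lambda_max_hz:
            raise ValueError("lambda_min must not exceed lambda_max")
        object.__setattr__(self, "theta", float(self.theta) % (2 * math.pi))


TuningModel = Union[LinearTuning, CosineTuning]


@dataclasses.dataclass
class SpikeTrain:
    """Binary spike indicators on a uniform (1 ms) clock."""

    spikes: np.ndarray
    sample_period_ms: float = SIM_PERIOD_MS

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes, dtype=np.uint8)
        if not np.all((self.spikes == 0) | (self.spikes == 1)):
            raise ValueError("spike entries must be 0 or 1")

    def __len__(self) -> int:
        return self.spikes.size

    def mean_rate_hz(self) -> float:
        return float(self.spikes.mean() * 1000.0 / self.sample_period_ms)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def make_block_stimulus(
    n_blocks: int, block_len_s: float, seed=0, sample_period_ms: float = SIM_PERIOD_MS
) -> TimeTrace:
    """Piecewise-constant stimulus: ``n_blocks`` blocks of Uniform(0,1) intensity.

    The default experiment concatenates 400 blocks of 5 s, a 2000 s
    (~30 minute) recording window.
    """
    if n_blocks < 1 or not block_len_s > 0:
        raise ValueError("need n_blocks >= 1 and positive block length")
    rng = _as_rng(seed)
    levels = rng.uniform(0.0, 1.0, size=n_blocks)
    per_block = int(round(block_len_s * 1000.0 / sample_period_ms))
    return TimeTrace(np.repeat(levels, per_block), sample_period_ms)


def _min_jerk_speed(n: int) -> np.ndarray:
    """Minimum-jerk speed profile on n samples, normalized to peak 1."""
    u = (np.arange(n) + 0.5) / n
    prof = 30.0 * u**2 * (1.0 - u) ** 2  # closed-form peak 1.875 at u = 1/2
    return prof / prof.max()  # normalize on the grid so the peak is attained exactly


def make_center_out_kinematics(
    n_reaches: int,
    directions: int = 8,
    reach_dur_ms: float = 600.0,
    hold_dur_ms: float = 400.0,
    peak_speed: float = 0.5,
    seed=0,
    randomize_order: bool = True,
) -> tuple[TimeTrace, TimeTrace]:
    """Synthetic center-out reach velocities at 1 ms.

    Each reach cycle is an outward minimum-jerk movement to one of
    ``directions`` uniformly spaced targets, a hold, a return movement in the
    opposite direction, and another hold.  Targets are block-randomized (a
    fresh permutation of all directions per block, reproducible per seed),
    as in real center-out sessions, so every direction is sampled equally
    often without making the session periodic; ``randomize_order=False``
    instead cycles targets 0, 1, 2, ... deterministically.  Returns x- and
    y-velocity traces in m/s.

    This generator is a synthetic stand-in emulating the statistical
    structure of a real center-out session: out-and-back reach pairs, a
    discrete set of directions, and speed profiles that spend time both
    above and below typical speed-gate thresholds.
    """
    if directions < 2:
        raise ValueError("need at least 2 reach directions")
    n_reach = int(round(reach_dur_ms / SIM_PERIOD_MS))
    n_hold = int(round(hold_dur_ms / SIM_PERIOD_MS))
    prof = _min_jerk_speed(n_reach) * peak_speed
    hold = np.zeros(n_hold)

    if randomize_order:
        rng = _as_rng(seed)
        n_blocks = math.ceil(n_reaches / directions)
        order = np.concatenate(
            [rng.permutation(directions) for _ in range(n_blocks)]
        )[:n_reaches]
    else:
        order = np.arange(n_reaches) % directions
    vx_parts, vy_parts = [], []
    for d in order:
        ang = 2.0 * math.pi * d / directions
        for sign in (1.0, -1.0):  # outward, then straight back
            vx_parts.append(sign * math.cos(ang) * prof)
            vy_parts.append(sign * math.sin(ang) * prof)
            vx_parts.append(hold)
            vy_parts.append(hold)
    vx = TimeTrace(np.concatenate(vx_parts), SIM_PERIOD_MS)
    vy = TimeTrace(np.concatenate(vy_parts), SIM_PERIOD_MS)
    return vx, vy


def speed_gate(
    vx: TimeTrace, vy: TimeTrace, lo: float = 0.05, hi: float = 0.4
) -> tuple[TimeTrace, TimeTrace, np.ndarray]:
    """Discard samples whose hand speed falls outside [lo, hi] m/s.

    Mirrors the preprocessing that drops samples where speed exceeds the
    upper threshold or falls below the lower one; survivors are concatenated
    onto a fresh clock.  Returns the gated traces plus the original sample
    indices that were kept.
    """
    if len(vx) != len(vy) or vx.sample_period_ms != vy.sample_period_ms:
        raise ValueError("vx and vy must share a clock")
    speed = np.hypot(vx.values, vy.values)
    keep = (speed >= lo) & (speed <= hi)
    if not keep.any():
        raise ValueError("speed gate removed every sample; unusable window")
    idx = np.flatnonzero(keep)
    p = vx.sample_period_ms
    return TimeTrace(vx.values[idx], p), TimeTrace(vy.values[idx], p), idx


def rate_from_tuning(g: TuningModel, covariates) -> TimeTrace:
    """Expected firing rate as spike probability per 1 ms bin.

    ``covariates`` is a single stimulus trace for linear tuning or a
    ``(vx, vy)`` pair for cosine tuning.  Rates are clipped at zero.
    """
    if g.kind == "linear":
        if isinstance(covariates, (tuple, list)):
            raise ValueError("linear tuning expects a single stimulus trace")
        stim = covariates
        lam = g.m * stim.values + g.lambda_min
        return TimeTrace(np.clip(lam, 0.0, None), stim.sample_period_ms, stim.t0_ms)
    vx, vy = covariates
    if len(vx) != len(vy) or vx.sample_period_ms != vy.sample_period_ms:
        raise ValueError("vx and vy must share a clock")
    speed = np.hypot(vx.values, vy.values)
    phi = np.arctan2(vy.values, vx.values)
    lam_hz = g.lambda_min_hz + (g.lambda_max_hz - g.lambda_min_hz) * (
        speed / g.ref_speed
    ) * 0.5 * (1.0 + np.cos(phi - g.theta))
    lam = np.clip(lam_hz, 0.0, None) / 1000.0  # spikes/s -> per 1 ms bin
    return TimeTrace(lam, vx.sample_period_ms, vx.t0_ms)


def sample_spikes(rate: TimeTrace, seed=0) -> SpikeTrain:
    """Independent Bernoulli spike per bin: s_t ~ Bernoulli(lambda_t)."""
    lam = rate.values
    if np.any(lam > 1.0):
        raise ValueError("rate exceeds 1 spike probability per bin; refine the clock")
    rng = _as_rng(seed)
    spikes = (rng.random(lam.size) < lam).astype(np.uint8)
    return SpikeTrain(spikes, rate.sample_period_ms)


def _exp_filter(x: np.ndarray, tau_ms: float, period_ms: float) -> np.ndarray:
    # causal convolution with exp(-t/tau), t >= 0, peak 1: recursive IIR form
    a = math.exp(-period_ms / tau_ms)
    return signal.lfilter([1.0], [1.0, -a], x)


def calcium_from_spikes(s: SpikeTrain, tau_ms: float = 200.0) -> TimeTrace:
    """Calcium transient trace: spikes convolved with exp(-t/tau).

    One isolated spike yields a decaying exponential of peak 1; the filter is
    linear, so overlapping transients superpose.
    """
    if not tau_ms > 0:
        raise ValueError("tau must be positive")
    c = _exp_filter(s.spikes.astype(np.float64), tau_ms, s.sample_period_ms)
    return TimeTrace(c, s.sample_period_ms)


def template_noise_stats(
    g: TuningModel, covariates, tau_ms: float = 200.0
) -> tuple[float, float]:
    """Attenuation and noise scale linking a template to spike-driven calcium.

    The template is the *expected* calcium (rate convolved with the kernel,
    standardized); real calcium adds spike noise filtered through the same
    kernel.  In standardized units the spike-driven calcium is approximately
    ``a * c_template + s * Z`` with ``Z`` standard normal, where

        a = sd(mu) / sqrt(sd(mu)^2 + var_eta),
        s = sqrt(var_eta) / sqrt(sd(mu)^2 + var_eta),

    ``mu`` the expected-calcium trace and ``var_eta`` the stationary filtered
    Bernoulli spike-noise variance ``mean(lambda (1 - lambda)) * sum(kernel^2)``.
    These statistics let the aligner marginalize its error-probability map
    over the calcium the template cannot predict.
    """
    rate = rate_from_tuning(g, covariates)
    lam = rate.values
    period = rate.sample_period_ms
    kernel_power = 1.0 / (1.0 - math.exp(-2.0 * period / tau_ms))
    var_eta = float(np.mean(lam * (1.0 - lam))) * kernel_power
    mu = _exp_filter(lam, tau_ms, period)
    sd_mu = float(mu.std())
    sd_tot = math.sqrt(sd_mu**2 + var_eta)
    if sd_tot == 0:
        return 0.0, 1.0
    return sd_mu / sd_tot, math.sqrt(var_eta) / sd_tot


def calcium_template(g: TuningModel, covariates, tau_ms: float = 200.0) -> TimeTrace:
    """Expected-calcium template: the *rate* (not sampled spikes) convolved
    with the calcium kernel, then standardized.

    This is the time-indexed prediction the aligner matches records against;
    standardization puts the sigmoid's half-maximum concentration at the
    trace midpoint.
    """
    rate = rate_from_tuning(g, covariates)
    c = _exp_filter(rate.values, tau_ms, rate.sample_period_ms)
    return TimeTrace(c, rate.sample_period_ms, rate.t0_ms).standardize()
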