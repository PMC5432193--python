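"""Shared fixtures.

Heavy simulation studies (the record-length sweep, the maximum-error-rate
sweep, the center-out study) are session-scoped so several tests can share
one run; their scales are desk-scale reductions of the published designs
(20 trials per grid point instead of 50; shorter center-out sessions).
"""

from __future__ import annotations

import numpy as np
import pytest

import tickertape as tt
from tickertape import experiments
from tickertape.config import center_out_config, parameter_evaluation_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def base_kinetics():
    """The ~100 Hz recorder with 2 s mean pauses (17% of time paused)."""
    return tt.KineticModel(p_pause=0.001, pause_mean_ms=2000.0, gamma_shape=1.0, gamma_scale_ms=10.0)


@pytest.fixture
def rising_sigmoid():
    """Error sigmoid rising with calcium: R_max 0.5, |b| 1, C_0 0."""
    return tt.ErrorFunction(r_max=0.5, b=-1.0, c0=0.0)


@pytest.fixture(scope="session")
def record_length_sweep():
    """Parameter-evaluation sweep over record length {1000, 2500, 5000} bp,
    20 strands per point (scaled down from the published 50)."""
    cfg = parameter_evaluation_config(
        n_trials=20,
        sweep={"axis": "record_length", "grid": [1000, 2500, 5000]},
        seed=1,
    )
    return experiments.run_parameter_sweep(cfg)


@pytest.fixture(scope="session")
def rmax_sweep():
    """Parameter-evaluation sweep over maximum error rate {0.05, 0.5} at
    2500 bp, 20 strands per point with matched per-trial seeds."""
    cfg = parameter_evaluation_config(
        n_trials=20,
        dnap={"n_basepairs": 2500},
        sweep={"axis": "r_max", "grid": [0.05, 0.5]},
        seed=1,
    )
    return experiments.run_parameter_sweep(cfg)


@pytest.fixture(scope="session")
def center_out_study():
    """Scaled-down center-out study: pausing, patch-shuffled, and
    pause-free arms on one shared session.

    One cosine-tuned neuron at theta = pi/4 (template id 1 of 8), 256
    reach cycles (~155 s gated), 6000 bp records, 12 trials per arm,
    matched per-trial seeds across arms.
    """
    base = dict(
        n_trials=12,
        neural={"n_reaches": 256},
        dnap={"n_basepairs": 6000},
        seed=0,
    )
    cfg = center_out_config(**base)
    res_orig, meta_orig = experiments.run_center_out(cfg)
    res_shuf, meta_shuf = experiments.run_center_out(cfg, shuffled=True)
    cfg_np = center_out_config(
        **{**base, "dnap": {"n_basepairs": 6000, "p_pause": 0.0}}
    )
    res_nopause, meta_nopause = experiments.run_center_out(cfg_np)
    return {
        "config": cfg,
        "true_id": 1,  # theta = pi/4 in the 8-direction ensemble
        "original": (res_orig, meta_orig),
        "shuffled": (res_shuf, meta_shuf),
        "pause_free": (res_nopause, meta_nopause),
    }
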