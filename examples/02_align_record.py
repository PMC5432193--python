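"""Align a recorded strand back to its calcium template and score timing.

The strand carries no clock; the aligner assigns each nucleotide an
incorporation time by matching the binned error pattern against the
expected-calcium template with a kinetics-constrained dynamic program,
then the recovered times are compared with the (normally hidden) truth.
"""

import numpy as np

import tickertape as tt
from tickertape import experiments
from tickertape.config import parameter_evaluation_config

cfg = parameter_evaluation_config(dnap={"n_basepairs": 5000}, seed=1)
rng = experiments.trial_rng(cfg.seed, 0)
session = experiments.linear_session(cfg, rng)
f = cfg.dnap.error_function()
kin = cfg.dnap.kinetic_model()

window = session["calcium"].duration_ms
times = tt.sample_incorporation_times(
    kin, window, tt.StartPrior(0.0, window / 4.0), cfg.dnap.n_basepairs, rng
)
record = tt.sample_errors(session["calcium"], times, f, rng)

alignment = tt.align(
    record.errors,
    session["template"],
    f,
    kin,
    cfg.alignment.alignment_config(),
    template_noise=session["template_noise"],
)

rmsd = tt.timing_rmsd(record.true_times_ms / 1e3, alignment.times_ms / 1e3)
ratio = tt.estimate_slope(
    record.errors, alignment.times_ms, session["stimulus"], f, session["calcium"]
)

print(f"strand: {record.n_basepairs} bp, true span "
      f"{times[0] / 1e3:.1f}-{times[-1] / 1e3:.1f} s of a {window / 1e3:.0f} s window")
print(f"estimated span        : {alignment.times_ms[0] / 1e3:.1f}-"
      f"{alignment.times_ms[-1] / 1e3:.1f} s")
print(f"path log-likelihood   : {alignment.log_likelihood:.1f}")
print(f"timing RMSD           : {rmsd:.2f} s "
      "(compare with the 5 s stimulus-block feature scale)")
print(f"tuning slope ratio    : {ratio:.2f} "
      "(recovered calcium-stimulus slope over its ground-truth value; ~1 is ideal)")
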