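"""Simulate a molecular-recorder strand from a stimulus-driven neuron.

A neuron with a linear stimulus tuning (m = 0.05 spikes/ms per unit
stimulus) fires against a block stimulus; its calcium modulates the error
rate of a ~100 Hz polymerase with 2 s pauses, and the errors written along
the growing strand are the recording.
"""

import numpy as np

import tickertape as tt

# 80 blocks of 5 s keeps this example quick (the full design uses 400)
stimulus = tt.make_block_stimulus(n_blocks=80, block_len_s=5.0, seed=1)
tuning = tt.LinearTuning(m=0.05, lambda_min=0.0)
rate = tt.rate_from_tuning(tuning, stimulus)
spikes = tt.sample_spikes(rate, seed=2)
calcium = tt.calcium_from_spikes(spikes, tau_ms=200.0).standardize()

kin = tt.KineticModel(p_pause=0.001, pause_mean_ms=2000.0, gamma_shape=1.0, gamma_scale_ms=10.0)
f = tt.ErrorFunction(r_max=0.5, b=-1.0, c0=0.0)  # error rate rises with calcium

window = calcium.duration_ms
times = tt.sample_incorporation_times(
    kin, window, tt.StartPrior(0.0, window / 4.0), n_max=2000, seed=3
)
record = tt.sample_errors(calcium, times, f, seed=4)

print(f"recording window       : {window / 1e3:.0f} s")
print(f"mean firing rate       : {spikes.mean_rate_hz():.1f} Hz")
print(f"expected incorporation : {1e3 / tt.expected_interval(kin):.0f} Hz")
print(f"time spent paused      : {100 * tt.paused_fraction(kin):.1f} %")
print(f"strand length          : {record.n_basepairs} bp "
      f"spanning {(times[-1] - times[0]) / 1e3:.1f} s")
print(f"errors on the strand   : {int(record.errors.sum())} "
      f"({100 * record.errors.mean():.1f} % of nucleotides)")

# the error rate should track calcium: compare the error fraction written
# at high- vs low-calcium moments
c_at_times = calcium.value_at(record.true_times_ms)
hi = record.errors[c_at_times > 0].mean()
lo = record.errors[c_at_times < 0].mean()
print(f"error fraction at high / low calcium: {hi:.2f} / {lo:.2f} "
      "(the recorder writes more errors when calcium is elevated)")
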