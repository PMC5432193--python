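"""How record length shapes timing accuracy: a miniature polymerase sweep.

Longer strands carry more of the stimulus pattern, so their alignments
lock onto the correct part of the recording window more reliably.  This
runs 6 strands at each of three record lengths (the full study uses 50).
"""

from tickertape import experiments
from tickertape.config import parameter_evaluation_config

cfg = parameter_evaluation_config(
    n_trials=6,
    sweep={"axis": "record_length", "grid": [1000, 2500, 5000]},
    seed=3,
)
trials = experiments.run_parameter_sweep(cfg)
summary = experiments.summarize_sweep(trials, seed=cfg.seed)

cols = ["value", "n_trials", "median_rmsd_s", "median_rmsd_lo", "median_rmsd_hi", "mean_slope_ratio"]
print(summary[cols].to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print()
print("median timing RMSD falls with record length (short records often")
print("cannot be located inside the 2000 s window at all); the tuning-slope")
print("ratio stays near 1 even where timing is poor, because tuning")
print("information survives imperfect alignment.")
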