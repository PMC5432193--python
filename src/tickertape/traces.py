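"""Uniformly sampled time series.

Every signal in the package -- delivered stimulus, firing rate, spike-derived
calcium, alignment templates, hand-velocity components -- is a scalar series
on a uniform clock. :class:`TimeTrace` is the shared container: a value
vector, a sample period in milliseconds, and a start offset, so the time of
sample ``i`` is ``t0_ms + i * sample_period_ms``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = ["TimeTrace", "read_kinematics_tsv", "write_kinematics_tsv"]


@dataclasses.dataclass
class TimeTrace:
    """A uniformly sampled scalar time series.

    Parameters
    ----------
    values : array-like of float
        Sample values, length >= 1.
    sample_period_ms : float
        Spacing between samples in milliseconds; must be positive.
    t0_ms : float, optional
        Time of the first sample (default 0).
    """

    values: np.ndarray
    sample_period_ms: float
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("TimeTrace requires a non-empty 1-D value array")
        if not self.sample_period_ms > 0:
            raise ValueError("sample_period_ms must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in milliseconds."""
        return self.t0_ms + np.arange(self.values.size) * self.sample_period_ms

    @property
    def duration_ms(self) -> float:
        """Window length T = (number of samples) * (sample period)."""
        return self.values.size * self.sample_period_ms

    def index_at(self, times_ms, clip: bool = False) -> np.ndarray:
        """Nearest-sample indices for the given times.

        Raises ``IndexError`` for times outside the trace support unless
        ``clip`` is true, in which case out-of-range times map to the edge
        samples.
        """
        t = np.atleast_1d(np.asarray(times_ms, dtype=np.float64))
        idx = np.rint((t - self.t0_ms) / self.sample_period_ms).astype(np.int64)
        if clip:
            return np.clip(idx, 0, self.values.size - 1)
        if np.any(idx < 0) or np.any(idx >= self.values.size):
            raise IndexError("requested time outside trace support")
        return idx

    def value_at(self, times_ms, clip: bool = False) -> np.ndarray:
        """Nearest-sample lookup of trace values at arbitrary times."""
        return self.values[self.index_at(times_ms, clip=clip)]

    def standardize(self) -> "TimeTrace":
        """Return a zero-mean, unit-variance copy (constant traces map to zeros).

        Standardization centres the trace so that a half-maximum concentration
        of zero sits at the trace midpoint, which is how the error sigmoid's
        ``c0 = 0`` convention is made meaningful for non-negative calcium.
        """
        v = self.values
        sd = v.std()
        if sd == 0:
            out = np.zeros_like(v)
        else:
            out = (v - v.mean()) / sd
        return TimeTrace(out, self.sample_period_ms, self.t0_ms)

    def to_tsv(self, path) -> None:
        """Write as a two-column (time_ms, value) TSV."""
        pd.DataFrame({"time_ms": self.times_ms, "value": self.values}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "TimeTrace":
        """Read a two-column (time_ms, value) TSV written by :meth:`to_tsv`."""
        df = pd.read_csv(path, sep="\t")
        t = df["time_ms"].to_numpy(dtype=np.float64)
        if t.size < 2:
            period = 1.0
        else:
            period = float(np.median(np.diff(t)))
        return cls(df["value"].to_numpy(dtype=np.float64), period, float(t[0]))


def write_kinematics_tsv(path, vx: TimeTrace, vy: TimeTrace) -> None:
    """Write x/y velocity components as a (time_ms, vx, vy) TSV."""
    if len(vx) != len(vy) or vx.sample_period_ms != vy.sample_period_ms:
        raise ValueError("vx and vy must share a clock")
    pd.DataFrame(
        {"time_ms": vx.times_ms, "vx": vx.values, "vy": vy.values}
    ).to_csv(path, sep="\t", index=False)


def read_kinematics_tsv(path) -> tuple[TimeTrace, TimeTrace]:
    """Read a (time_ms, vx, vy) TSV into a pair of velocity traces."""
    df = pd.read_csv(path, sep="\t")
    t = df["time_ms"].to_numpy(dtype=np.float64)
    period = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    vx = TimeTrace(df["vx"].to_numpy(dtype=np.float64), period, float(t[0]))
    vy = TimeTrace(df["vy"].to_numpy(dtype=np.float64), period, float(t[0]))
    return vx, vy
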