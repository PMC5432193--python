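"""The molecular recorder itself: incorporation times, errors, and strands.

The generative model: a recording start time tau_1 is drawn from a uniform
prior over an early slice of the window; each subsequent incorporation time
is tau_n = tau_{n-1} + U with U drawn from the polymerase's pause/extension
mixture; and each nucleotide independently misincorporates with probability
f(c_{tau_n}), the error transfer function evaluated at the (standardized)
calcium concentration when it was written.  Only the binary error strand D
is observable after sequencing; the incorporation times are ground truth
available to simulations alone.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dnap import ErrorFunction, KineticModel, sample_intervals
from .traces import TimeTrace

__all__ = [
    "RecorderOutput",
    "StartPrior",
    "sample_incorporation_times",
    "sample_errors",
    "random_template_seq",
    "strand_to_fasta",
    "fasta_to_strand",
    "write_strand_tsv",
    "read_strand_tsv",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclasses.dataclass(frozen=True)
class StartPrior:
    """Uniform prior over the recording start time, in ms."""

    lo_ms: float
    hi_ms: float

    def __post_init__(self) -> None:
        if not 0 <= self.lo_ms < self.hi_ms:
            raise ValueError("need 0 <= lo < hi for the start prior")


@dataclasses.dataclass
class RecorderOutput:
    """A binary error strand with its (hidden) ground-truth incorporation times."""

    errors: np.ndarray
    true_times_ms: np.ndarray

    def __post_init__(self) -> None:
        self.errors = np.asarray(self.errors, dtype=np.uint8)
        self.true_times_ms = np.asarray(self.true_times_ms, dtype=np.float64)
        if self.errors.size != self.true_times_ms.size:
            raise ValueError("errors and true_times must have equal length")
        if self.true_times_ms.size > 1 and not np.all(np.diff(self.true_times_ms) > 0):
            raise ValueError("true incorporation times must be strictly increasing")

    @property
    def n_basepairs(self) -> int:
        return self.errors.size


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_incorporation_times(
    kin: KineticModel,
    window_ms: float,
    prior: StartPrior,
    n_max: int,
    seed=0,
) -> np.ndarray:
    """Draw strictly increasing incorporation times inside the window.

    tau_1 comes from the start prior; subsequent times accumulate continuous
    mixture intervals.  Generation stops at ``n_max`` nucleotides or at the
    window edge, whichever comes first; a truncated record is returned with
    a logged warning rather than an error.
    """
    if not window_ms > 0:
        raise ValueError("window must be positive")
    if prior.hi_ms > window_ms:
        raise ValueError("start prior extends beyond the recording window")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    rng = _as_rng(seed)
    t1 = rng.uniform(prior.lo_ms, prior.hi_ms)
    if n_max == 1:
        return np.array([t1])
    times = t1 + np.concatenate(
        [[0.0], np.cumsum(sample_intervals(kin, n_max - 1, rng))]
    )
    inside = times <= window_ms
    if not inside.all():
        times = times[inside]
        logger.warning(
            "record truncated by window: %d of %d nucleotides fit in %.0f ms",
            times.size,
            n_max,
            window_ms,
        )
    return times


def sample_errors(
    calcium: TimeTrace, times_ms: np.ndarray, f: ErrorFunction, seed=0
) -> RecorderOutput:
    """Draw the error strand: d_n ~ Bernoulli(f(c at tau_n)).

    Calcium is looked up at the nearest sample (the 1 ms grid is far finer
    than the 200 ms calcium dynamics, so interpolation is unnecessary).
    """
    times_ms = np.asarray(times_ms, dtype=np.float64)
    c = calcium.value_at(times_ms)
    rng = _as_rng(seed)
    d = rng.random(times_ms.size) < f(c)
    return RecorderOutput(d.astype(np.uint8), times_ms)


def random_template_seq(n: int, seed=0) -> str:
    """A uniform-random ACGT template strand of length n."""
    rng = _as_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


def strand_to_fasta(
    rec: RecorderOutput, template_seq: str, seed=0
) -> tuple[SeqRecord, SeqRecord]:
    """Render the error strand as a template/copy FASTA pair.

    The copy is written position-for-position against the template: correct
    incorporations carry the Watson-Crick complement of the template base,
    errors carry a uniformly random non-complementary base.  Round-trips
    through :func:`fasta_to_strand`.
    """
    template_seq = template_seq.upper()
    n = rec.n_basepairs
    if len(template_seq) < n:
        raise ValueError("template sequence shorter than the strand")
    if any(b not in _COMPLEMENT for b in template_seq[:n]):
        raise ValueError("template contains non-ACGT characters")
    rng = _as_rng(seed)
    copy = []
    for base, err in zip(template_seq[:n], rec.errors):
        comp = _COMPLEMENT[base]
        if err:
            others = [b for b in "ACGT" if b != comp]
            copy.append(others[rng.integers(3)])
        else:
            copy.append(comp)
    template = SeqRecord(Seq(template_seq[:n]), id="template", description="")
    copied = SeqRecord(Seq("".join(copy)), id="copy", description="")
    return template, copied


def fasta_to_strand(template: SeqRecord, copy: SeqRecord) -> np.ndarray:
    """Position-wise mismatch indicator from a template/copy pair.

    A position is an error (1) when the copy base is not the Watson-Crick
    complement of the template base.
    """
    t = str(template.seq).upper()
    c = str(copy.seq).upper()
    if len(t) != len(c):
        raise ValueError("template and copy have different lengths")
    bad = set(t + c) - set("ACGT")
    if bad:
        raise ValueError(f"invalid characters in sequences: {sorted(bad)}")
    return np.array(
        [0 if cb == _COMPLEMENT[tb] else 1 for tb, cb in zip(t, c)], dtype=np.uint8
    )


def write_fasta_pair(path_template, path_copy, template: SeqRecord, copy: SeqRecord):
    SeqIO.write([template], path_template, "fasta")
    SeqIO.write([copy], path_copy, "fasta")


def read_fasta_pair(path_template, path_copy) -> tuple[SeqRecord, SeqRecord]:
    return (
        next(SeqIO.parse(path_template, "fasta")),
        next(SeqIO.parse(path_copy, "fasta")),
    )


def write_strand_tsv(path, rec: RecorderOutput, *, hide_times: bool = False) -> None:
    """Serialize a strand as TSV; true times are optional (blinded output)."""
    import pandas as pd

    cols = {"index": np.arange(rec.n_basepairs), "error": rec.errors}
    if not hide_times:
        cols["true_time_ms"] = rec.true_times_ms
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_strand_tsv(path) -> RecorderOutput:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    errors = df["error"].to_numpy(dtype=np.uint8)
    if "true_time_ms" in df.columns:
        times = df["true_time_ms"].to_numpy(dtype=np.float64)
    else:
        times = np.arange(errors.size, dtype=np.float64)  # placeholder clock
    return RecorderOutput(errors, times)
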