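"""Per-second heart-rate conversion.

For each 1-s interval ``k`` (half-open windows ``[k, k+1)`` s anchored at
the signal start) the R-R records whose terminating beat falls inside the
window are averaged, and the interval's heart rate is

    BPM[k] = 60000 / mean R-R [k]   (R-R in ms)

Intervals with no records carry the last computed value forward (flagged
``filled``, matching a live display that holds its last reading); leading
empty intervals are NaN and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .qrs import RRSeries


@dataclass
class BPMSeries:
    """Per-1-second heart-rate series.

    ``k`` is contiguous from 0; ``bpm[k] * meanRR[k] == 60000`` wherever
    ``n_rr[k] > 0``.
    """

    k: np.ndarray          # interval index
    bpm: np.ndarray        # beats/min (NaN for leading missing intervals)
    n_rr: np.ndarray       # R-R records per interval
    filled: np.ndarray     # True where no record fell in the interval

    def __post_init__(self):
        self.k = np.asarray(self.k, dtype=int)
        self.bpm = np.asarray(self.bpm, dtype=float)
        self.n_rr = np.asarray(self.n_rr, dtype=int)
        self.filled = np.asarray(self.filled, dtype=bool)
        if not (self.k.size == self.bpm.size == self.n_rr.size == self.filled.size):
            raise ValidationError("BPMSeries fields must have equal length")
        if self.k.size and not np.array_equal(self.k, np.arange(self.k.size)):
            raise ValidationError("interval indices must be contiguous from 0")

    @property
    def n_intervals(self) -> int:
        return self.k.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.k, "bpm": self.bpm, "n_rr": self.n_rr, "filled": self.filled}
        )


def bpm_series(rr: RRSeries, duration_s: float) -> BPMSeries:
    """Convert an R-R series to the per-second BPM series.

    ``duration_s`` fixes the number of intervals (``floor(duration_s)``);
    records beyond it are ignored.  Raises if no interval contains a record.
    """
    if duration_s < 1:
        raise ValidationError(f"duration must be at least 1 s, got {duration_s}")
    n = int(np.floor(duration_s))
    idx = np.floor(rr.t / 1000.0).astype(int)
    valid = (idx >= 0) & (idx < n)
    idx, vals = idx[valid], rr.rr[valid]

    n_rr = np.bincount(idx, minlength=n)
    sums = np.bincount(idx, weights=vals, minlength=n)
    if not np.any(n_rr > 0):
        raise ValidationError("no R-R records fall inside the series span; no heart rate computable")

    bpm = np.full(n, np.nan)
    populated = n_rr > 0
    bpm[populated] = 60000.0 / (sums[populated] / n_rr[populated])
    # carry the last computed value forward; leading gaps stay NaN
    last = np.nan
    for i in range(n):
        if populated[i]:
            last = bpm[i]
        else:
            bpm[i] = last
    return BPMSeries(k=np.arange(n), bpm=bpm, n_rr=n_rr, filled=~populated)
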