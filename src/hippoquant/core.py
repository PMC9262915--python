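"""Shared domain types: uniformly sampled signals, interval sets, event tables.

Conventions used throughout the package:

* time is in seconds, sample indices are 0-based, and the time of sample
  ``i`` of a :class:`UniformSignal` is ``t0_s + i / rate_hz``;
* intervals are half-open ``[start, end)`` so adjacent intervals never
  double-count samples; a sample belongs to an interval iff
  ``start <= t < end`` evaluated on the exact sample timestamp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UniformSignal",
    "IntervalSet",
    "EventTable",
    "restrict",
    "zscore",
    "resample_linear",
]

VALID_UNITS = ("mV", "pA", "a.u.", "dimensionless", "%", "m/s", "m/s^2")


@dataclass(frozen=True)
class UniformSignal:
    """One uniformly sampled real-valued channel.

    Parameters
    ----------
    values : array-like of float
        The samples.  Must be finite.
    rate_hz : float
        Sampling rate, > 0.
    t0_s : float, optional
        Time of sample 0 (seconds).
    units : str, optional
        Physical units of the samples (e.g. ``"mV"``, ``"pA"``, ``"a.u."``).
    """

    values: np.ndarray
    rate_hz: float
    t0_s: float = 0.0
    units: str = "a.u."

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.all(np.isfinite(vals)):
            raise ValueError("signal values must be finite")
        if not (self.rate_hz > 0):
            raise ValueError(f"rate_hz must be > 0, got {self.rate_hz}")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.rate_hz

    @property
    def duration_s(self) -> float:
        """Span of the signal, ``n / rate`` (the half-open support)."""
        return self.n / self.rate_hz

    @property
    def t_end_s(self) -> float:
        return self.t0_s + self.duration_s

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n) / self.rate_hz

    def with_values(self, values: np.ndarray, units: str | None = None) -> "UniformSignal":
        """Same clock, new samples (and optionally new units)."""
        return UniformSignal(values, self.rate_hz, self.t0_s,
                             self.units if units is None else units)


class IntervalSet:
    """Ordered, pairwise-disjoint half-open time intervals ``[start, end)``."""

    def __init__(self, intervals: Iterable[tuple[float, float]] = ()):  # noqa: D107
        arr = np.asarray(list(intervals), dtype=np.float64)
        if arr.size == 0:
            arr = np.empty((0, 2), dtype=np.float64)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("intervals must be (start, end) pairs")
        if np.any(arr[:, 0] >= arr[:, 1]):
            raise ValueError("every interval must satisfy start < end")
        order = np.argsort(arr[:, 0], kind="stable")
        arr = arr[order]
        if arr.shape[0] > 1 and np.any(arr[1:, 0] < arr[:-1, 1]):
            raise ValueError("intervals must be pairwise disjoint")
        self._arr = arr

    @property
    def starts(self) -> np.ndarray:
        return self._arr[:, 0]

    @property
    def ends(self) -> np.ndarray:
        return self._arr[:, 1]

    def as_array(self) -> np.ndarray:
        return self._arr.copy()

    def __len__(self) -> int:
        return self._arr.shape[0]

    def __iter__(self):
        return iter(map(tuple, self._arr))

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._arr.shape == other._arr.shape and np.array_equal(self._arr, other._arr)

    def __repr__(self) -> str:
        return f"IntervalSet({[tuple(p) for p in self._arr]!r})"

    def duration(self) -> float:
        """Total covered time."""
        return float(np.sum(self._arr[:, 1] - self._arr[:, 0]))

    def contains(self, t: np.ndarray | float) -> np.ndarray | bool:
        """Half-open membership of time(s) ``t``."""
        t = np.asarray(t, dtype=np.float64)
        scalar = t.ndim == 0
        tt = np.atleast_1d(t)
        # index of the last interval starting at or before t
        idx = np.searchsorted(self._arr[:, 0], tt, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(tt.shape, dtype=bool)
        if self._arr.shape[0]:
            inside[ok] = tt[ok] < self._arr[idx[ok], 1]
        return bool(inside[0]) if scalar else inside

    def complement(self, span: tuple[float, float]) -> "IntervalSet":
        """Gaps of this set within ``span = (lo, hi)``.

        ``duration(self within span) + duration(complement)`` equals the span
        length exactly when the set lies inside the span.
        """
        lo, hi = float(span[0]), float(span[1])
        if lo >= hi:
            raise ValueError("span must satisfy lo < hi")
        gaps: list[tuple[float, float]] = []
        cursor = lo
        for s, e in self._arr:
            s, e = max(s, lo), min(e, hi)
            if s >= e:
                continue
            if s > cursor:
                gaps.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < hi:
            gaps.append((cursor, hi))
        return IntervalSet(gaps)

    def intersect_span(self, span: tuple[float, float]) -> "IntervalSet":
        lo, hi = span
        clipped = [(max(s, lo), min(e, hi)) for s, e in self._arr]
        return IntervalSet([(s, e) for s, e in clipped if s < e])

    @classmethod
    def from_mask(cls, mask: np.ndarray, rate_hz: float, t0_s: float = 0.0) -> "IntervalSet":
        """Maximal runs of True in a boolean sample mask, as time intervals.

        A run covering samples ``[i, j]`` becomes ``[t(i), t(j) + dt)`` so the
        intervals of a mask and of its negation partition the signal span.
        """
        mask = np.asarray(mask, dtype=bool)
        if mask.size == 0:
            return cls()
        edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
        starts = np.r_[0, edges + 1][np.r_[mask[0], mask[edges + 1]]]
        stops = np.r_[edges, mask.size - 1][np.r_[mask[edges], mask[-1]]] + 1
        dt = 1.0 / rate_hz
        return cls([(t0_s + s * dt, t0_s + e * dt) for s, e in zip(starts, stops)])

    def to_csv(self, path) -> None:
        pd.DataFrame(self._arr, columns=["start_s", "end_s"]).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "IntervalSet":
        df = pd.read_csv(path)
        return cls(list(zip(df["start_s"], df["end_s"])))


class EventTable:
    """Detected or ground-truth events with onset/peak/offset times.

    Thin wrapper over a :class:`pandas.DataFrame` with required columns
    ``onset_s``, ``peak_s``, ``offset_s``, ``amplitude`` plus arbitrary
    per-event measures.  Rows are kept sorted by onset.
    """

    REQUIRED = ("onset_s", "peak_s", "offset_s", "amplitude")

    def __init__(self, df: pd.DataFrame | None = None, **columns):
        if df is None:
            df = pd.DataFrame(columns)
        df = pd.DataFrame(df)
        for col in self.REQUIRED:
            if col not in df.columns:
                if len(df):
                    raise ValueError(f"EventTable missing column {col!r}")
                df[col] = pd.Series(dtype=float)
        if len(df):
            if not ((df["onset_s"] <= df["peak_s"]).all()
                    and (df["peak_s"] <= df["offset_s"]).all()):
                raise ValueError("events must satisfy onset <= peak <= offset")
            if not np.all(np.isfinite(df["amplitude"].to_numpy(dtype=float))):
                raise ValueError("amplitudes must be finite")
            df = df.sort_values("onset_s", kind="stable").reset_index(drop=True)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __getitem__(self, col: str) -> np.ndarray:
        return self.df[col].to_numpy()

    @classmethod
    def empty(cls) -> "EventTable":
        return cls(pd.DataFrame(columns=list(cls.REQUIRED)))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "EventTable":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# operations


def restrict(signal: UniformSignal, ivs: IntervalSet) -> np.ndarray:
    """Concatenated samples of ``signal`` whose timestamps fall in ``ivs``.

    Order is preserved.  An empty overlap yields an empty array; an interval
    reaching outside the signal span raises.
    """
    lo, hi = signal.t0_s, signal.t_end_s
    tol = 0.5 * signal.dt  # guard against float round-off at span edges
    pieces: list[np.ndarray] = []
    for s, e in ivs:
        if s < lo - tol or e > hi + tol:
            raise ValueError(
                f"interval ({s}, {e}) outside signal span ({lo}, {hi})")
        # first sample with t >= s and first with t >= e
        i0 = int(np.ceil((s - signal.t0_s) * signal.rate_hz - 1e-9))
        i1 = int(np.ceil((e - signal.t0_s) * signal.rate_hz - 1e-9))
        i0, i1 = max(i0, 0), min(i1, signal.n)
        if i1 > i0:
            pieces.append(signal.values[i0:i1])
    if not pieces:
        return np.empty(0, dtype=np.float64)
    return np.concatenate(pieces)


def zscore(values: Sequence[float] | np.ndarray, mu: float, sd: float) -> np.ndarray:
    """Standardize ``values`` with the given mean and standard deviation."""
    if not (sd > 0):
        raise ValueError(f"sd must be > 0, got {sd}")
    return (np.asarray(values, dtype=np.float64) - mu) / sd


def resample_linear(signal: UniformSignal, new_rate_hz: float) -> UniformSignal:
    """Linear interpolation of ``signal`` onto a new uniform grid.

    The new grid starts at ``t0_s`` with spacing ``1/new_rate_hz`` and covers
    the same time range (last old sample included when the rates are
    commensurate, so resampling to the same rate is the identity).
    """
    if not (new_rate_hz > 0):
        raise ValueError("new_rate_hz must be > 0")
    if signal.n < 2:
        raise ValueError("signal must have at least 2 samples to resample")
    t_last = signal.t0_s + (signal.n - 1) / signal.rate_hz
    n_new = int(np.floor((t_last - signal.t0_s) * new_rate_hz + 1e-9)) + 1
    t_new = signal.t0_s + np.arange(n_new) / new_rate_hz
    vals = np.interp(t_new, signal.times(), signal.values)
    return UniformSignal(vals, new_rate_hz, signal.t0_s, signal.units)
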