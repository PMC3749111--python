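"""Velocity-threshold trial segmentation and trial exclusion filters.

A trial starts when the tangential velocity of the tracked joint first
exceeds 5% of that trial's maximum and ends when it falls back below.  The
rule is circular as stated (the per-trial maximum needs trial boundaries),
so it is realized in two passes: candidate movement bursts are found with a
global 5%-of-session-maximum threshold, bursts closer than ``min_gap`` are
merged (dwell pauses inside a reach cycle are not trial boundaries), and
each burst's boundaries are then refined against that burst's own maximum.
Crossings are resolved at sample resolution; the first crossing wins ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TrialSet", "segment_trials", "exclude_by_displacement"]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class TrialSet:
    """Disjoint, sorted [start, end) sample intervals on the feature grid."""

    intervals: list[tuple[int, int]]
    fs: float
    excluded: list[tuple[tuple[int, int], str]] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.intervals)

    def mask(self, n_samples: int, trials: "list[int] | None" = None) -> np.ndarray:
        """Boolean series marking samples inside the selected trials."""
        m = np.zeros(n_samples, dtype=bool)
        idx = range(len(self.intervals)) if trials is None else trials
        for i in idx:
            s, e = self.intervals[i]
            m[s:e] = True
        return m

    def durations_s(self) -> np.ndarray:
        return np.array([(e - s) / self.fs for s, e in self.intervals])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"start_s": s / self.fs, "end_s": e / self.fs, "status": "used", "reason": ""}
            for s, e in self.intervals
        ] + [
            {"start_s": s / self.fs, "end_s": e / self.fs, "status": "excluded", "reason": r}
            for (s, e), r in self.excluded
        ]
        return pd.DataFrame(rows, columns=["start_s", "end_s", "status", "reason"])

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _bursts(above: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) runs of True."""
    d = np.diff(above.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def segment_trials(
    speed: np.ndarray,
    fs: float,
    threshold_fraction: float = 0.05,
    min_gap: float = 1.5,
    min_duration: float = 2.0,
) -> TrialSet:
    """Segment a speed series into movement trials.

    Parameters
    ----------
    speed : nonnegative speed series (m/s).
    threshold_fraction : velocity threshold relative to the maximum (0.05
        = the 5% rule).
    min_gap : bursts separated by less than this (seconds) are merged.
    min_duration : merged intervals shorter than this (seconds) are dropped.
    """
    speed = np.asarray(speed, dtype=float)
    if np.any(speed < -1e-12):
        raise ValueError("speed must be nonnegative")
    if not (0 < threshold_fraction < 1):
        raise ValueError("threshold_fraction must lie in (0, 1)")
    vmax = speed.max(initial=0.0)
    if vmax <= 0:
        return TrialSet(intervals=[], fs=fs)

    # pass 1: global threshold, then merge across short gaps
    cand = _bursts(speed > threshold_fraction * vmax)
    merged: list[tuple[int, int]] = []
    gap = int(round(min_gap * fs))
    for s, e in cand:
        if merged and s - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    # pass 2: refine each burst against its own maximum.  The per-burst
    # threshold is never above the global one, so refinement expands the
    # boundaries outward to the burst's own 5% crossings, bounded by the
    # neighbouring bursts.
    out: list[tuple[int, int]] = []
    min_len = int(round(min_duration * fs))
    n = speed.size
    for i, (s, e) in enumerate(merged):
        local_thr = threshold_fraction * speed[s:e].max()
        left_bound = out[-1][1] if out else 0
        right_bound = merged[i + 1][0] if i + 1 < len(merged) else n
        s2, e2 = s, e
        while s2 > left_bound and speed[s2 - 1] > local_thr:
            s2 -= 1
        while e2 < right_bound and speed[e2] > local_thr:
            e2 += 1
        if e2 - s2 >= min_len:
            out.append((s2, e2))
    return TrialSet(intervals=out, fs=fs)


def exclude_by_displacement(
    trials: TrialSet,
    markers: np.ndarray,
    axis: str = "y",
    limit: float = 0.20,
) -> TrialSet:
    """Move trials with excessive within-trial marker excursion to excluded.

    A trial whose marker range along ``axis`` exceeds ``limit`` meters is
    excluded with reason "displacement" — e.g. a 20 cm sagittal limit flags
    trials contaminated by torso sway.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}")
    if not limit > 0:
        raise ValueError("limit must be positive")
    markers = np.atleast_2d(np.asarray(markers, dtype=float))
    col = markers[:, _AXES[axis]]
    kept: list[tuple[int, int]] = []
    excluded = list(trials.excluded)
    for s, e in trials.intervals:
        if np.ptp(col[s:e]) > limit:
            excluded.append(((s, e), "displacement"))
        else:
            kept.append((s, e))
    return TrialSet(intervals=kept, fs=trials.fs, excluded=excluded)
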