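"""Growth half-times (t50) from OD600 time courses.

t50 is the time a culture needs to reach half-maximal OD600, read off the
replicate-mean curve by linear interpolation between the bracketing
samples; delta-t50 between strains measures growth inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class GrowthIncompleteError(ValueError):
    """The curve never reaches its half-maximal OD600."""


@dataclass
class GrowthCurve:
    """OD600 per time point per replicate."""

    time_h: np.ndarray
    od600: np.ndarray
    replicate_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.replicate_id is None:
            self.replicate_id = np.zeros(self.time_h.shape, dtype=int)
        self.replicate_id = np.asarray(self.replicate_id)
        if not (self.time_h.shape == self.od600.shape == self.replicate_id.shape):
            raise ValueError("time_h, od600 and replicate_id must share a shape")
        if np.any(self.od600 < 0):
            raise ValueError("OD600 must be non-negative")
        for rep in np.unique(self.replicate_id):
            t = self.time_h[self.replicate_id == rep]
            if t.size < 3:
                raise ValueError("each replicate needs >= 3 time points")
            if np.any(np.diff(t) <= 0):
                raise ValueError("time must be strictly increasing within a replicate")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GrowthCurve":
        frame = frame.sort_values(["replicate", "time_h"]) if "replicate" in frame else frame
        return cls(
            time_h=frame["time_h"].to_numpy(),
            od600=frame["od600"].to_numpy(),
            replicate_id=(
                frame["replicate"].to_numpy() if "replicate" in frame else None
            ),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_h": self.time_h, "od600": self.od600, "replicate": self.replicate_id}
        )

    def mean_curve(self) -> tuple[np.ndarray, np.ndarray]:
        """Replicate-mean OD on the common time grid."""
        frame = pd.DataFrame({"time_h": self.time_h, "od600": self.od600})
        grouped = frame.groupby("time_h", sort=True)["od600"].mean()
        return grouped.index.to_numpy(), grouped.to_numpy()


@dataclass(frozen=True)
class GrowthFeatures:
    t50_h: float
    od_max: float
    od_min: float


def _first_crossing(time: np.ndarray, od: np.ndarray, level: float) -> float:
    """First upward crossing of ``level``, linearly interpolated."""
    above = od >= level
    if above[0]:
        raise GrowthIncompleteError("curve starts at or above the half-maximal level")
    idx = np.nonzero(above)[0]
    if idx.size == 0:
        raise GrowthIncompleteError("growth incomplete: half-maximal OD never reached")
    i = idx[0]
    t0, t1 = time[i - 1], time[i]
    y0, y1 = od[i - 1], od[i]
    return float(t0 + (level - y0) / (y1 - y0) * (t1 - t0))


def t50(curve: GrowthCurve, log_scale: bool = False) -> GrowthFeatures:
    """Half-maximal growth time on the replicate-mean curve.

    The half level is od_min + (od_max - od_min)/2 with od_min the minimum
    of the mean curve (robust to the inoculation OD); ``log_scale`` applies
    the same rule to log-transformed OD as a sensitivity variant.
    """
    time, od = curve.mean_curve()
    values = np.log(np.maximum(od, 1e-6)) if log_scale else od
    od_min, od_max = float(values.min()), float(values.max())
    level = od_min + (od_max - od_min) / 2.0
    t50_h = _first_crossing(time, values, level)
    return GrowthFeatures(t50_h=t50_h, od_max=float(od.max()), od_min=float(od.min()))


def t50_per_replicate(curve: GrowthCurve, log_scale: bool = False) -> pd.DataFrame:
    """t50 per labeled replicate, for mean +/- SD aggregation across cultures."""
    rows = []
    for rep in np.unique(curve.replicate_id):
        mask = curve.replicate_id == rep
        sub = GrowthCurve(curve.time_h[mask], curve.od600[mask])
        rows.append({"replicate": rep, "t50_h": t50(sub, log_scale=log_scale).t50_h})
    return pd.DataFrame(rows)


def delta_t50(a: GrowthFeatures | float, b: GrowthFeatures | float) -> float:
    """Signed half-time difference a - b in hours (positive = a grows slower)."""
    ta = a.t50_h if isinstance(a, GrowthFeatures) else float(a)
    tb = b.t50_h if isinstance(b, GrowthFeatures) else float(b)
    return ta - tb
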