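"""Scalar readouts of the Ca2+ release transient.

Rest [Ca2+] is the level at the end of the Ca2+-free wash, just before
permeabilization; Peak [Ca2+] is the maximum of the release transient that
permeabilization evokes.  The first derivative of the transient separates
the fast (free organellar Ca2+) and slow (matrix-bound, largely vacuolar)
release components; two resolvable derivative peaks classify the transient
as biphasic, one as quasi-monophasic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .traces import CalciumTrace

DEFAULT_SMOOTHING_WINDOW_S = 11.0
DEFAULT_PROMINENCE_FRAC = 0.15
DEFAULT_MIN_SEPARATION_S = 30.0
DEFAULT_REST_WINDOW_S = 10.0


@dataclass(frozen=True)
class DerivativeComponent:
    """One release component, located by its derivative peak."""

    derivative_peak_time_s: float  # seconds after permeabilization onset
    derivative_peak_rate: float  # molar per second


@dataclass(frozen=True)
class ReleaseFeatures:
    rest_ca: float
    peak_ca: float
    time_to_peak_s: float
    decay_half_time_s: float | None
    classification: str  # biphasic | quasi-monophasic | none
    components: tuple[DerivativeComponent, ...]

    def to_row(self, trace_id: str = "") -> dict:
        """Features as a table row, concentrations in micromolar."""
        return {
            "trace_id": trace_id,
            "rest_ca_um": self.rest_ca * 1e6,
            "peak_ca_um": self.peak_ca * 1e6,
            "time_to_peak_s": self.time_to_peak_s,
            "decay_half_time_s": (
                np.nan if self.decay_half_time_s is None else self.decay_half_time_s
            ),
            "classification": self.classification,
            "n_components": len(self.components),
        }


@dataclass(frozen=True)
class DerivativeProfile:
    time_s: np.ndarray  # seconds after permeabilization onset
    d_ca_dt: np.ndarray
    smoothing_window_s: float


def rest_ca(trace: CalciumTrace, window_s: float = DEFAULT_REST_WINDOW_S) -> float:
    """Mean valid [Ca2+] over the final ``window_s`` of the Ca2+-free wash."""
    seg = trace.protocol.segment("ca_free")
    if seg.duration_s < window_s:
        raise ValueError(
            f"ca_free segment ({seg.duration_s} s) shorter than window ({window_s} s)"
        )
    mask = (
        trace.protocol.mask("ca_free")
        & (trace.time_s >= seg.end_s - window_s)
        & trace.valid
    )
    if not np.any(mask):
        raise ValueError("no valid bins in the rest window")
    return float(trace.ca_molar[mask].mean())


def _smooth(values: np.ndarray, window_bins: int) -> np.ndarray:
    """Moving average with edge-shrinking windows (no phase shift)."""
    kernel = np.ones(window_bins) / window_bins
    padded = np.pad(values, window_bins // 2, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def _window_bins(smoothing_window_s: float, bin_width_s: float) -> int:
    window = int(round(smoothing_window_s / bin_width_s))
    if window < 3 or window % 2 == 0:
        raise ValueError("smoothing window must span an odd number of bins, >= 3")
    return window


def derivative_profile(
    trace: CalciumTrace, smoothing_window_s: float = DEFAULT_SMOOTHING_WINDOW_S
) -> DerivativeProfile:
    """Smoothed first derivative of the permeabilized-segment trace.

    Centered differences after a moving average; one-sided differences at
    the endpoints.
    """
    window = _window_bins(smoothing_window_s, trace.protocol.bin_width_s)
    mask = trace.protocol.mask("permeabilized")
    if mask.sum() < window:
        raise ValueError("permeabilized segment shorter than the smoothing window")
    t = trace.time_s[mask] - trace.protocol.segment("permeabilized").start_s
    smoothed = _smooth(trace.ca_molar[mask], window)
    d = np.gradient(smoothed, t)
    return DerivativeProfile(time_s=t, d_ca_dt=d, smoothing_window_s=smoothing_window_s)


def release_features(
    trace: CalciumTrace,
    smoothing_window_s: float = DEFAULT_SMOOTHING_WINDOW_S,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
    rest_window_s: float = DEFAULT_REST_WINDOW_S,
) -> ReleaseFeatures:
    """Extract Rest/Peak [Ca2+], kinetics and phase classification.

    The peak search covers the permeabilized segment only — the terminal
    discharge is a calibration maneuver, not a biological transient.
    Components are positive local maxima of the smoothed derivative with
    prominence >= ``prominence_frac`` of the derivative maximum and pairwise
    separation >= ``min_separation_s``, truncated to the two largest.
    """
    perm = trace.protocol.segment("permeabilized")
    mask = trace.protocol.mask("permeabilized") & trace.valid
    if mask.sum() * trace.protocol.bin_width_s < 60.0:
        raise ValueError("permeabilized segment must provide >= 60 s of valid bins")

    rest = rest_ca(trace, rest_window_s)
    values = trace.ca_molar[mask]
    times = trace.time_s[mask]
    i_peak = int(np.argmax(values))
    peak = float(values[i_peak])
    time_to_peak = float(times[i_peak] - perm.start_s)

    half_level = rest + (peak - rest) / 2.0
    after = values[i_peak:]
    below = np.nonzero(after <= half_level)[0]
    decay_half: float | None = None
    if below.size:
        decay_half = float(times[i_peak + below[0]] - times[i_peak])

    profile = derivative_profile(trace, smoothing_window_s)
    d = profile.d_ca_dt
    components: tuple[DerivativeComponent, ...] = ()
    if np.any(d > 0) and peak > rest:
        distance = max(1, int(round(min_separation_s / trace.protocol.bin_width_s)))
        idx, _ = find_peaks(
            d, prominence=prominence_frac * d.max(), distance=distance
        )
        idx = idx[d[idx] > 0]
        if idx.size > 2:
            idx = idx[np.argsort(d[idx])[-2:]]
        idx = np.sort(idx)
        components = tuple(
            DerivativeComponent(float(profile.time_s[i]), float(d[i])) for i in idx
        )

    classification = {2: "biphasic", 1: "quasi-monophasic", 0: "none"}[len(components)]
    return ReleaseFeatures(
        rest_ca=rest,
        peak_ca=peak,
        time_to_peak_s=time_to_peak,
        decay_half_time_s=decay_half,
        classification=classification,
        components=components,
    )


def features_table(
    traces: dict[str, CalciumTrace] | list[CalciumTrace], **kwargs
) -> pd.DataFrame:
    """One features row per trace (concentrations in micromolar)."""
    if not isinstance(traces, dict):
        traces = {str(i): tr for i, tr in enumerate(traces)}
    rows = [release_features(tr, **kwargs).to_row(tid) for tid, tr in traces.items()]
    return pd.DataFrame(rows)
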