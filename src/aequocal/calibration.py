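"""Aequorin luminescence -> cytosolic [Ca2+] calibration.

Aequorin is consumed by the photon it emits, so raw luminescence L cannot be
compared across time: it must be normalised to the luminescence the remaining
photoprotein could still produce (Lmax).  The fractional luminescence
L/Lmax maps to [Ca2+] through the three-site occupancy model

    L/Lmax = ((1 + K_R*Ca) / (1 + K_TR + K_R*Ca))**3

where K_R and K_TR are the equilibrium constants of the Ca2+-bound and
Ca2+-unbound states.  With f = (L/Lmax)**(1/3) the exact inverse is

    Ca = (f*(1 + K_TR) - 1) / (K_R*(1 - f))

Lmax is resolved as the *remaining* integral of the record (current bin to
end) scaled by the saturating consumption rate constant: consumption makes
the denominator time-dependent, and the terminal Triton + 10 mM Ca2+
discharge guarantees the remaining integral counts all surviving aequorin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traces import (
    INVALID_BELOW_DOMAIN,
    INVALID_LMAX_EXHAUSTED,
    INVALID_SATURATED,
    AveragedTrace,
    CalciumTrace,
    FractionalTrace,
    PhotonTrace,
)

#: aequorin equilibrium constants from the classical calibration literature;
#: overridable through CalibrationConstants / the [calibration] config section.
DEFAULT_K_R = 7.23e6  # per molar, Ca2+-bound state
DEFAULT_K_TR = 120.0  # dimensionless, Ca2+-unbound state
DEFAULT_LAMBDA_SAT = 1.0  # per second, consumption rate at saturating Ca2+

#: remaining-integral floor below which L/Lmax is dominated by shot noise
DEFAULT_LMAX_FLOOR_COUNTS = 100.0
#: fractional-luminescence cube-root ceiling treated as saturated
DEFAULT_F_MAX = 0.999


@dataclass(frozen=True)
class CalibrationConstants:
    k_r: float = DEFAULT_K_R
    k_tr: float = DEFAULT_K_TR
    lambda_sat: float = DEFAULT_LAMBDA_SAT
    background_rate: float = 0.0
    lmax_floor_counts: float = DEFAULT_LMAX_FLOOR_COUNTS
    f_max: float = DEFAULT_F_MAX
    #: a bin consuming more than this fraction of the remaining quanta breaks
    #: the rate-based L/Lmax estimate (only the terminal discharge does)
    max_bin_consumption: float = 0.05

    def __post_init__(self) -> None:
        if self.k_r <= 0 or self.k_tr <= 0:
            raise ValueError("k_r and k_tr must be positive")
        if self.lambda_sat <= 0:
            raise ValueError("lambda_sat must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be non-negative")
        if not 0 < self.f_max < 1:
            raise ValueError("f_max must lie in (0, 1)")

    @property
    def f_floor(self) -> float:
        """Cube-root fractional luminescence at Ca = 0 (domain boundary)."""
        return 1.0 / (1.0 + self.k_tr)


def occupancy_fraction(ca_molar, k_r: float = DEFAULT_K_R, k_tr: float = DEFAULT_K_TR):
    """Forward occupancy model: expected L/Lmax at a given [Ca2+].

    Strictly increasing in Ca, bounded in ((1/(1+k_tr))**3, 1).
    """
    ca = np.asarray(ca_molar, dtype=float)
    if k_r <= 0 or k_tr <= 0:
        raise ValueError("k_r and k_tr must be positive")
    return ((1.0 + k_r * ca) / (1.0 + k_tr + k_r * ca)) ** 3


def estimate_fractional_luminescence(
    trace: PhotonTrace, constants: CalibrationConstants | None = None
) -> FractionalTrace:
    """Compute per-bin fractional luminescence L/Lmax from a photon record.

    L_i is the background-corrected count rate in bin i; Lmax_i is
    lambda_sat times the remaining background-corrected counts from bin i to
    the end of the record (remaining-integral convention).  Requires the
    record to end in a discharge segment, otherwise Lmax is undefined.
    """
    constants = constants or CalibrationConstants()
    labels = trace.protocol.segment_labels()
    if "discharge" not in labels:
        raise ValueError("record has no discharge segment; Lmax is undefined")
    dt = trace.protocol.bin_width_s
    corrected = np.maximum(trace.counts.astype(float) - constants.background_rate * dt, 0.0)
    if not np.any(corrected > 0):
        raise ValueError("all-zero photon record after background correction")

    remaining = np.cumsum(corrected[::-1])[::-1]
    l_rate = corrected / dt
    lmax = constants.lambda_sat * remaining
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lmax > 0, l_rate / lmax, np.inf)

    valid = np.ones(ratio.shape, dtype=bool)
    reason = np.full(ratio.shape, "", dtype=object)

    exhausted = remaining < constants.lmax_floor_counts
    valid[exhausted] = False
    reason[exhausted] = INVALID_LMAX_EXHAUSTED

    cap = constants.f_max**3
    with np.errstate(invalid="ignore", divide="ignore"):
        consumed_frac = np.where(remaining > 0, corrected / remaining, 1.0)
    saturated = ((ratio > cap) | (consumed_frac > constants.max_bin_consumption)) & ~exhausted
    valid[saturated] = False
    reason[saturated] = INVALID_SATURATED

    ratio = np.clip(ratio, 0.0, cap)
    return FractionalTrace(
        time_s=trace.time_s.copy(),
        l_over_lmax=ratio,
        valid=valid,
        invalid_reason=reason,
        protocol=trace.protocol,
    )


def allen_calibrate(
    fractional: FractionalTrace, constants: CalibrationConstants | None = None
) -> CalciumTrace:
    """Invert the cubed-occupancy model: fractional luminescence -> [Ca2+].

    Bins with f <= 1/(1+k_tr) (formally Ca <= 0) are clamped to 0 and
    flagged ``below-domain``; f >= f_max is flagged ``saturated``.
    """
    constants = constants or CalibrationConstants()
    f = fractional.f_cuberoot
    valid = fractional.valid.copy()
    reason = np.array(fractional.invalid_reason, dtype=object, copy=True)

    below = f <= constants.f_floor
    saturated = f >= constants.f_max

    with np.errstate(divide="ignore", invalid="ignore"):
        ca = (f * (1.0 + constants.k_tr) - 1.0) / (constants.k_r * (1.0 - f))
    ca = np.where(below, 0.0, ca)

    newly_below = below & valid
    valid[newly_below] = False
    reason[newly_below] = INVALID_BELOW_DOMAIN
    newly_sat = saturated & valid
    valid[newly_sat] = False
    reason[newly_sat] = INVALID_SATURATED

    return CalciumTrace(
        time_s=fractional.time_s.copy(),
        ca_molar=ca,
        protocol=fractional.protocol,
        valid=valid,
        invalid_reason=reason,
    )


def calibrate(
    trace: PhotonTrace, constants: CalibrationConstants | None = None
) -> CalciumTrace:
    """Full photon record -> calibrated [Ca2+] trace (both stages)."""
    constants = constants or CalibrationConstants()
    return allen_calibrate(estimate_fractional_luminescence(trace, constants), constants)


def average_traces(traces: list[CalciumTrace]) -> AveragedTrace:
    """Per-bin mean and SEM (SD/sqrt(n)) over replicate calibrated traces.

    A bin is averaged over the traces in which it is valid; bins invalid in
    every trace are carried as NaN.
    """
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    t0 = traces[0].time_s
    for tr in traces[1:]:
        if tr.time_s.shape != t0.shape or not np.allclose(tr.time_s, t0):
            raise ValueError("replicate traces must share an identical time grid")

    values = np.stack([tr.ca_molar for tr in traces])
    valid = np.stack([tr.valid for tr in traces])
    masked = np.ma.masked_array(values, mask=~valid)
    n_valid = valid.sum(axis=0)
    mean = np.where(n_valid > 0, masked.mean(axis=0).filled(np.nan), np.nan)
    sd = masked.std(axis=0, ddof=1).filled(0.0) if len(traces) > 1 else np.zeros_like(mean)
    with np.errstate(invalid="ignore", divide="ignore"):
        sem = np.where(n_valid > 1, sd / np.sqrt(np.maximum(n_valid, 1)), 0.0)
    return AveragedTrace(
        time_s=t0.copy(),
        mean_ca=mean,
        sem_ca=sem,
        n=len(traces),
        protocol=traces[0].protocol,
    )
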