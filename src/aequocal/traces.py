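"""In-memory containers for luminometer records and calibrated Ca2+ traces."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import PerfusionProtocol

#: reasons a calibrated bin may be flagged invalid
INVALID_BELOW_DOMAIN = "below-domain"
INVALID_LMAX_EXHAUSTED = "lmax-exhausted"
INVALID_SATURATED = "saturated"


@dataclass
class PhotonTrace:
    """Photon counts per integration bin plus the protocol annotation."""

    time_s: np.ndarray
    counts: np.ndarray
    protocol: PerfusionProtocol

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.time_s.shape != self.counts.shape:
            raise ValueError("time_s and counts must have the same shape")
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be non-negative")
        dt = np.diff(self.time_s)
        if self.time_s.size > 1 and not np.allclose(dt, self.protocol.bin_width_s):
            raise ValueError("time grid must be uniform at protocol.bin_width_s")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "counts": self.counts,
                "segment": self.protocol.segment_labels(),
            }
        )


@dataclass
class FractionalTrace:
    """Fractional luminescence L/Lmax and its cube root, per bin."""

    time_s: np.ndarray
    l_over_lmax: np.ndarray
    valid: np.ndarray
    invalid_reason: np.ndarray
    protocol: PerfusionProtocol

    @property
    def f_cuberoot(self) -> np.ndarray:
        return np.cbrt(self.l_over_lmax)


@dataclass
class CalciumTrace:
    """Calibrated cytosolic [Ca2+] in molar units on the protocol time grid."""

    time_s: np.ndarray
    ca_molar: np.ndarray
    protocol: PerfusionProtocol
    valid: np.ndarray = None
    invalid_reason: np.ndarray = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.ca_molar = np.asarray(self.ca_molar, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.time_s.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.invalid_reason is None:
            self.invalid_reason = np.full(self.time_s.shape, "", dtype=object)
        if self.time_s.shape != self.ca_molar.shape:
            raise ValueError("time_s and ca_molar must have the same shape")
        if np.any(self.ca_molar[self.valid] < 0):
            raise ValueError("valid ca_molar values must be non-negative")

    def segment_values(self, label: str, valid_only: bool = True) -> np.ndarray:
        mask = self.protocol.mask(label)
        if valid_only:
            mask = mask & self.valid
        return self.ca_molar[mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time_s, "ca_molar": self.ca_molar, "valid": self.valid}
        )


@dataclass
class AveragedTrace:
    """Replicate mean +/- SEM trace (n = number of coverslips/replicates)."""

    time_s: np.ndarray
    mean_ca: np.ndarray
    sem_ca: np.ndarray
    n: int
    protocol: PerfusionProtocol

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "mean_ca": self.mean_ca,
                "sem_ca": self.sem_ca,
                "n": self.n,
            }
        )
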