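"""CSV round-tripping for the pipeline's tabular artifacts."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .growth import GrowthCurve
from .protocol import PerfusionProtocol, Segment
from .qpcr import QpcrPlate
from .traces import AveragedTrace, CalciumTrace, PhotonTrace


def write_photon_trace(trace: PhotonTrace, path: str | Path) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_photon_trace(path: str | Path, bin_width_s: float = 1.0) -> PhotonTrace:
    """Read a `time_s, counts, segment` CSV, rebuilding the protocol from
    the segment annotation."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"photon trace CSV not found: {path}")
    frame = pd.read_csv(path)
    protocol = _protocol_from_segments(frame, bin_width_s)
    return PhotonTrace(
        time_s=frame["time_s"].to_numpy(dtype=float),
        counts=frame["counts"].to_numpy(),
        protocol=protocol,
    )


def _protocol_from_segments(frame: pd.DataFrame, bin_width_s: float) -> PerfusionProtocol:
    segments = []
    for label, sub in frame.groupby("segment", sort=False):
        start = float(sub["time_s"].min())
        end = float(sub["time_s"].max()) + bin_width_s
        segments.append(Segment(label, start, end))
    segments.sort(key=lambda s: s.start_s)
    return PerfusionProtocol(segments=tuple(segments), bin_width_s=bin_width_s)


def write_calcium_trace(trace: CalciumTrace, path: str | Path) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_calcium_trace(path: str | Path, protocol: PerfusionProtocol) -> CalciumTrace:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"calcium trace CSV not found: {path}")
    frame = pd.read_csv(path)
    valid = (
        frame["valid"].to_numpy(dtype=bool)
        if "valid" in frame
        else np.ones(len(frame), dtype=bool)
    )
    return CalciumTrace(
        time_s=frame["time_s"].to_numpy(dtype=float),
        ca_molar=frame["ca_molar"].to_numpy(dtype=float),
        protocol=protocol,
        valid=valid,
    )


def write_averaged_trace(trace: AveragedTrace, path: str | Path) -> None:
    trace.to_frame().to_csv(path, index=False)


def write_growth_curve(curve: GrowthCurve, path: str | Path) -> None:
    curve.to_frame().to_csv(path, index=False)


def read_growth_curve(path: str | Path) -> GrowthCurve:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"growth CSV not found: {path}")
    return GrowthCurve.from_frame(pd.read_csv(path))


def write_qpcr_plate(plate: QpcrPlate, path: str | Path) -> None:
    plate.data.to_csv(path, index=False)


def read_qpcr_plate(
    path: str | Path, reference_gene: str, calibrator_condition: str
) -> QpcrPlate:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"qPCR plate CSV not found: {path}")
    return QpcrPlate(
        pd.read_csv(path),
        reference_gene=reference_gene,
        calibrator_condition=calibrator_condition,
    )
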