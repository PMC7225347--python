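"""Perfusion protocol: the timed segment structure of an aequorin experiment.

A recording walks through five phases: baseline perfusion (``pre``), a
high-external-Ca2+ challenge (``external_ca``), a Ca2+-free wash
(``ca_free``), detergent permeabilization releasing stored Ca2+
(``permeabilized``), and a terminal discharge of all remaining aequorin
(``discharge``) which anchors the Lmax normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SEGMENT_ORDER = ("pre", "external_ca", "ca_free", "permeabilized", "discharge")


@dataclass(frozen=True)
class Segment:
    label: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class PerfusionProtocol:
    """Ordered, contiguous segmentation of the recording time axis.

    Parameters
    ----------
    segments
        One :class:`Segment` per label in :data:`SEGMENT_ORDER`, contiguous
        and strictly increasing.
    bin_width_s
        Photon-integration bin width in seconds (1 s on the instrument).
    """

    segments: tuple[Segment, ...]
    bin_width_s: float = 1.0

    def __post_init__(self) -> None:
        labels = [s.label for s in self.segments]
        if labels != list(SEGMENT_ORDER):
            raise ValueError(
                f"protocol must contain exactly the segments {list(SEGMENT_ORDER)} "
                f"in order, got {labels}"
            )
        if self.bin_width_s <= 0:
            raise ValueError("bin_width_s must be positive")
        for seg in self.segments:
            if not seg.end_s > seg.start_s:
                raise ValueError(f"segment {seg.label!r} must have end_s > start_s")
        for a, b in zip(self.segments, self.segments[1:]):
            if not np.isclose(a.end_s, b.start_s):
                raise ValueError(
                    f"segments {a.label!r} and {b.label!r} are not contiguous"
                )

    @classmethod
    def from_durations(
        cls,
        pre_s: float = 60.0,
        external_ca_s: float = 120.0,
        ca_free_s: float = 90.0,
        permeabilized_s: float = 600.0,
        discharge_s: float = 60.0,
        bin_width_s: float = 1.0,
    ) -> "PerfusionProtocol":
        """Build a protocol from segment durations.

        Defaults follow the standard yeast protocol: a 2 min 10 mM external
        Ca2+ pulse, a 90 s Ca2+-free wash, then Triton permeabilization.
        """
        durations = (pre_s, external_ca_s, ca_free_s, permeabilized_s, discharge_s)
        edges = np.concatenate([[0.0], np.cumsum(durations)])
        segments = tuple(
            Segment(label, float(a), float(b))
            for label, a, b in zip(SEGMENT_ORDER, edges[:-1], edges[1:])
        )
        return cls(segments=segments, bin_width_s=bin_width_s)

    def segment(self, label: str) -> Segment:
        for seg in self.segments:
            if seg.label == label:
                return seg
        raise KeyError(label)

    @property
    def total_duration_s(self) -> float:
        return self.segments[-1].end_s - self.segments[0].start_s

    def time_grid(self) -> np.ndarray:
        """Left edges of the photon-integration bins covering the protocol."""
        start = self.segments[0].start_s
        n = int(round(self.total_duration_s / self.bin_width_s))
        return start + np.arange(n) * self.bin_width_s

    def segment_labels(self) -> np.ndarray:
        """Segment label for every bin of :meth:`time_grid`."""
        t = self.time_grid()
        labels = np.empty(t.shape, dtype=object)
        for seg in self.segments:
            labels[(t >= seg.start_s) & (t < seg.end_s)] = seg.label
        return labels.astype(str)

    def mask(self, label: str) -> np.ndarray:
        seg = self.segment(label)
        t = self.time_grid()
        return (t >= seg.start_s) & (t < seg.end_s)
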