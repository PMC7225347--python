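"""Forward models generating synthetic study data.

Three generators mirror the three experimental readouts:

* :func:`generate_ca_trajectory` + :func:`simulate_photon_trace` — a
  deterministic cytosolic [Ca2+] trajectory following the perfusion
  protocol, pushed through an aequorin photon-counting model (occupancy
  factor, irreversible consumption, Poisson shot noise);
* :func:`simulate_growth` — logistic OD600 growth curves with Gaussian
  measurement noise;
* :func:`simulate_qpcr` — Cq plates under the exponential amplification
  model with per-gene primer efficiencies.

Named presets bundle protocol + release parameters reproducing the four
qualitative phenotypes of the study system: biphasic wild-type release,
the quasi-monophasic alpha-synuclein phenotype, the fast-component-only
pmc1 deletion, and the low-rest biphasic vcx1 deletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .calibration import DEFAULT_K_R, DEFAULT_K_TR, occupancy_fraction
from .protocol import PerfusionProtocol
from .traces import CalciumTrace, PhotonTrace


class ProtocolMismatchError(ValueError):
    """Release parameters are inconsistent with the perfusion protocol."""


# ---------------------------------------------------------------------------
# release pulse shape
# ---------------------------------------------------------------------------
#
# Each component is a sigmoid-onset pulse
#
#     g(t) = (1 - exp(-t/tau_r))**m * exp(-t/tau_d)
#
# peak-normalised to 1 at its time-to-peak.  m = 1 is the classical
# difference of exponentials, whose steepest rise sits at t = 0; larger
# onset powers m delay the inflection, which is what separates the fast and
# slow humps in the first-derivative profile of a biphasic transient.
# The peak time is closed-form: t* = tau_r * ln((m*tau_d + tau_r)/tau_r).


def _pulse_peak_time(rise_tau_s: float, decay_tau_s: float, onset_power: float) -> float:
    r, d, m = rise_tau_s, decay_tau_s, onset_power
    return r * np.log((m * d + r) / r)


def rise_tau_for_peak(
    decay_tau_s: float, time_to_peak_s: float, onset_power: float = 2.0
) -> float:
    """Rise time constant placing the pulse peak exactly at ``time_to_peak_s``.

    The peak time grows monotonically with the rise tau, from 0 toward
    ``onset_power * decay_tau_s``; this inverts that relation.
    """
    if not 0 < time_to_peak_s < onset_power * decay_tau_s:
        raise ValueError(
            "time_to_peak_s must lie in (0, onset_power * decay_tau_s)"
        )
    return brentq(
        lambda r: _pulse_peak_time(r, decay_tau_s, onset_power) - time_to_peak_s,
        1e-12 * decay_tau_s,
        1e6 * decay_tau_s,
        xtol=1e-12,
    )


@dataclass(frozen=True)
class ReleaseComponent:
    """One kinetic component of the store-release transient.

    ``amplitude`` and ``time_to_peak_s`` are exact: the pulse is
    peak-normalised to 1 at ``time_to_peak_s``, which therefore must be the
    natural peak of the (rise, decay, onset) triple — use
    :func:`rise_tau_for_peak` or :meth:`from_peak`.
    """

    amplitude_molar: float
    time_to_peak_s: float
    rise_tau_s: float
    decay_tau_s: float
    onset_power: float = 2.0

    def __post_init__(self) -> None:
        if self.amplitude_molar < 0:
            raise ValueError("amplitude must be non-negative")
        if self.rise_tau_s <= 0 or self.decay_tau_s <= 0:
            raise ValueError("rise_tau_s and decay_tau_s must be positive")
        if self.onset_power < 1:
            raise ValueError("onset_power must be >= 1")
        natural = _pulse_peak_time(self.rise_tau_s, self.decay_tau_s, self.onset_power)
        if abs(natural - self.time_to_peak_s) > 0.5:
            raise ValueError(
                f"time_to_peak_s={self.time_to_peak_s} inconsistent with the "
                f"pulse shape peak {natural:.2f} s; use rise_tau_for_peak"
            )

    @classmethod
    def from_peak(
        cls,
        amplitude_molar: float,
        time_to_peak_s: float,
        decay_tau_s: float,
        onset_power: float = 2.0,
    ) -> "ReleaseComponent":
        return cls(
            amplitude_molar=amplitude_molar,
            time_to_peak_s=time_to_peak_s,
            rise_tau_s=rise_tau_for_peak(decay_tau_s, time_to_peak_s, onset_power),
            decay_tau_s=decay_tau_s,
            onset_power=onset_power,
        )

    def waveform(self, t_s: np.ndarray) -> np.ndarray:
        """Peak-normalised pulse evaluated at times since permeabilization."""
        t = np.maximum(np.asarray(t_s, dtype=float), 0.0)
        g = (1.0 - np.exp(-t / self.rise_tau_s)) ** self.onset_power * np.exp(
            -t / self.decay_tau_s
        )
        tp = self.time_to_peak_s
        norm = (1.0 - np.exp(-tp / self.rise_tau_s)) ** self.onset_power * np.exp(
            -tp / self.decay_tau_s
        )
        return self.amplitude_molar * g / norm


@dataclass(frozen=True)
class ReleaseModelParams:
    """Phenomenological parameters of a cytosolic Ca2+ trajectory."""

    baseline_ca: float = 1.0e-7
    external_ca_plateau: float = 5.3e-7
    rest_ca: float = 5.0e-8
    ca_free_decay_tau: float = 15.0
    components: tuple[ReleaseComponent, ...] = ()
    discharge_ca: float = 1.0e-2

    def __post_init__(self) -> None:
        for name in ("baseline_ca", "external_ca_plateau", "rest_ca", "discharge_ca"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.ca_free_decay_tau <= 0:
            raise ValueError("ca_free_decay_tau must be positive")
        peaks = [c.time_to_peak_s for c in self.components]
        if peaks != sorted(peaks):
            raise ValueError("components must be sorted by time_to_peak_s")


def generate_ca_trajectory(
    protocol: PerfusionProtocol, params: ReleaseModelParams
) -> CalciumTrace:
    """Deterministic ground-truth [Ca2+](t) on the protocol's time grid.

    Baseline during ``pre``; instantaneous step to the plateau during
    ``external_ca``; exponential relaxation toward ``rest_ca`` during
    ``ca_free``; rest plus the sum of peak-normalised release pulses during
    ``permeabilized``; saturating ``discharge_ca`` during ``discharge``.
    """
    perm = protocol.segment("permeabilized")
    for comp in params.components:
        if comp.time_to_peak_s >= perm.duration_s:
            raise ProtocolMismatchError(
                f"component time_to_peak_s={comp.time_to_peak_s} s falls beyond "
                f"the permeabilized segment ({perm.duration_s} s long)"
            )

    t = protocol.time_grid()
    ca = np.full(t.shape, params.baseline_ca)

    ca[protocol.mask("external_ca")] = params.external_ca_plateau

    free = protocol.segment("ca_free")
    m = protocol.mask("ca_free")
    ca[m] = params.rest_ca + (params.external_ca_plateau - params.rest_ca) * np.exp(
        -(t[m] - free.start_s) / params.ca_free_decay_tau
    )

    m = protocol.mask("permeabilized")
    release = np.full(m.sum(), params.rest_ca)
    for comp in params.components:
        release = release + comp.waveform(t[m] - perm.start_s)
    ca[m] = release

    ca[protocol.mask("discharge")] = params.discharge_ca
    return CalciumTrace(time_s=t, ca_molar=ca, protocol=protocol)


# ---------------------------------------------------------------------------
# aequorin photon counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AequorinParams:
    """Photophysics of the reconstituted aequorin pool.

    ``initial_quanta`` is the number of photons the pool can still emit at
    t = 0; ``lambda_sat`` the consumption rate constant at saturating Ca2+.
    ``detection_efficiency`` cancels in L/Lmax and exists to test exactly
    that cancellation.
    """

    initial_quanta: float = 1.0e8
    lambda_sat: float = 1.0
    k_r: float = DEFAULT_K_R
    k_tr: float = DEFAULT_K_TR
    background_rate: float = 0.0
    detection_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.initial_quanta <= 0:
            raise ValueError("initial_quanta must be positive")
        if self.lambda_sat <= 0:
            raise ValueError("lambda_sat must be positive")
        if self.k_r <= 0 or self.k_tr <= 0:
            raise ValueError("k_r and k_tr must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be non-negative")
        if not 0 < self.detection_efficiency <= 1:
            raise ValueError("detection_efficiency must lie in (0, 1]")


def expected_photon_counts(
    ca: CalciumTrace, aeq: AequorinParams
) -> np.ndarray:
    """Noise-free expected signal counts per bin (no background).

    Per bin i: f_i = occupancy_fraction(Ca_i); the remaining pool decays as
    N_{i+1} = N_i exp(-lambda_sat f_i dt) and the bin emits
    detection_efficiency * N_i * (1 - exp(-lambda_sat f_i dt)) counts in
    expectation.  The telescoping sum conserves quanta: over a record run to
    exhaustion the expected counts total detection_efficiency * N0.
    """
    if not np.all(np.isfinite(ca.ca_molar)):
        raise ValueError("Ca trace contains non-finite values")
    dt = ca.protocol.bin_width_s
    f = occupancy_fraction(ca.ca_molar, aeq.k_r, aeq.k_tr)
    decay = aeq.lambda_sat * f * dt
    # N_i = N0 * exp(-sum_{j<i} decay_j)
    n_remaining = aeq.initial_quanta * np.exp(-np.concatenate([[0.0], np.cumsum(decay[:-1])]))
    return aeq.detection_efficiency * n_remaining * (-np.expm1(-decay))


def simulate_photon_trace(
    ca: CalciumTrace, aeq: AequorinParams | None = None, seed: int | None = None
) -> PhotonTrace:
    """Poisson photon-count record of a Ca2+ trajectory.

    The seed is mandatory: simulated records are reproducibility contracts,
    and an identical seed yields a bitwise-identical record.
    """
    if seed is None:
        raise ValueError("seed is required for simulate_photon_trace")
    aeq = aeq or AequorinParams()
    labels = ca.protocol.segment_labels()
    if labels[-1] != "discharge":
        raise ValueError("Ca trace must end in a discharge segment")
    expected = expected_photon_counts(ca, aeq)
    dt = ca.protocol.bin_width_s
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected + aeq.background_rate * dt)
    return PhotonTrace(time_s=ca.time_s.copy(), counts=counts, protocol=ca.protocol)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_UM = 1e-6

def _preset_params() -> dict[str, ReleaseModelParams]:
    # fast component: sharp onset, peak ~50 s; slow component: delayed
    # sigmoidal onset (large onset power), peak ~2 min 20 s
    fast = ReleaseComponent.from_peak(0.45 * _UM, 50.0, 40.0, onset_power=8.0)
    slow = ReleaseComponent.from_peak(1.20 * _UM, 140.0, 150.0, onset_power=40.0)
    return {
        # wild type: complete decay to a near-zero rest, biphasic release,
        # slow component dominant, peak ~1.3 uM around 2 min 20 s
        "wild_type_biphasic": ReleaseModelParams(
            baseline_ca=0.10 * _UM,
            external_ca_plateau=0.53 * _UM,
            rest_ca=0.05 * _UM,
            ca_free_decay_tau=15.0,
            components=(fast, slow),
        ),
        # alpha-synuclein: elevated rest (incomplete decay), one dominant
        # fast-shifted component peaking ~75 s, higher peak, faster decay
        "alpha_syn_monophasic": ReleaseModelParams(
            baseline_ca=0.10 * _UM,
            external_ca_plateau=0.775 * _UM,
            rest_ca=0.29 * _UM,
            ca_free_decay_tau=20.0,
            components=(ReleaseComponent.from_peak(1.78 * _UM, 75.0, 90.0, onset_power=8.0),),
        ),
        # pmc1 deletion: fast component only, reduced peak, elevated rest
        "pmc1_null_fast_only": ReleaseModelParams(
            baseline_ca=0.10 * _UM,
            external_ca_plateau=0.53 * _UM,
            rest_ca=0.19 * _UM,
            ca_free_decay_tau=15.0,
            components=(ReleaseComponent.from_peak(0.75 * _UM, 50.0, 40.0, onset_power=8.0),),
        ),
        # vcx1 deletion: very low rest, biphasic release minimally affected
        "vcx1_null_biphasic": ReleaseModelParams(
            baseline_ca=0.10 * _UM,
            external_ca_plateau=0.53 * _UM,
            rest_ca=0.05 * _UM,
            ca_free_decay_tau=15.0,
            components=(fast, replace(slow, amplitude_molar=1.26 * _UM)),
        ),
    }


PRESET_NAMES = tuple(_preset_params())


def preset(name: str) -> tuple[PerfusionProtocol, ReleaseModelParams]:
    """Protocol + release parameters for a named strain phenotype."""
    presets = _preset_params()
    if name not in presets:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {sorted(presets)}"
        )
    return PerfusionProtocol.from_durations(), presets[name]


# ---------------------------------------------------------------------------
# growth and qPCR simulators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthModelParams:
    """Logistic OD600 growth with Gaussian measurement noise."""

    od_floor: float = 0.01
    od_max: float = 1.2
    rate_k: float = 0.25  # per hour
    midpoint_h: float = 30.0
    noise_sd: float = 0.01
    duration_h: float = 72.0
    sample_interval_h: float = 0.5

    def __post_init__(self) -> None:
        if not self.od_max > self.od_floor >= 0:
            raise ValueError("need od_max > od_floor >= 0")
        if self.rate_k <= 0:
            raise ValueError("rate_k must be positive")
        if self.duration_h <= 0 or self.sample_interval_h <= 0:
            raise ValueError("duration_h and sample_interval_h must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def simulate_growth(
    params: GrowthModelParams, seed: int | None = None, n_replicates: int = 3
):
    """Seeded replicate OD600 growth curves (triplicate cultures by default)."""
    from .growth import GrowthCurve  # local import: growth does not import synthetic

    if seed is None:
        raise ValueError("seed is required for simulate_growth")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, params.duration_h + 1e-9, params.sample_interval_h)
    logistic = params.od_floor + (params.od_max - params.od_floor) / (
        1.0 + np.exp(-params.rate_k * (t - params.midpoint_h))
    )
    time, od, rep = [], [], []
    for r in range(n_replicates):
        noisy = logistic + rng.normal(0.0, params.noise_sd, size=t.shape)
        time.append(t)
        od.append(np.maximum(noisy, 0.0))
        rep.append(np.full(t.shape, r))
    return GrowthCurve(
        time_h=np.concatenate(time),
        od600=np.concatenate(od),
        replicate_id=np.concatenate(rep),
    )


@dataclass(frozen=True)
class QpcrSimParams:
    """Cq plate simulation under the exponential amplification model."""

    true_ratio: float = 2.0
    efficiency_target: float = 1.85
    efficiency_ref: float = 1.91
    cq_base: float = 24.0
    replicate_sd: float = 0.15
    n_replicates: int = 6

    def __post_init__(self) -> None:
        if self.true_ratio <= 0:
            raise ValueError("true_ratio must be positive")
        if not 1 < self.efficiency_target <= 2 or not 1 < self.efficiency_ref <= 2:
            raise ValueError("efficiencies must lie in (1, 2] fold per cycle")
        if self.n_replicates < 3:
            raise ValueError("need at least 3 replicates")


def simulate_qpcr(
    params: QpcrSimParams,
    seed: int | None = None,
    target_gene: str = "PMC1",
    reference_gene: str = "ACT1",
    calibrator_condition: str = "control",
    test_condition: str = "treated",
):
    """Simulate a two-condition Cq plate with a known expression ratio.

    A ``true_ratio``-fold higher template shifts the target Cq of the test
    condition by -log(true_ratio)/log(E_target) cycles; the reference gene
    is equal across conditions in expectation.
    """
    from .qpcr import QpcrPlate  # local import

    if seed is None:
        raise ValueError("seed is required for simulate_qpcr")
    rng = np.random.default_rng(seed)
    shift = -np.log(params.true_ratio) / np.log(params.efficiency_target)
    ref_base = params.cq_base - 4.0
    rows = []
    for cond, target_cq in (
        (calibrator_condition, params.cq_base),
        (test_condition, params.cq_base + shift),
    ):
        for rep in range(params.n_replicates):
            rows.append(
                (cond, target_gene, rep, target_cq + rng.normal(0.0, params.replicate_sd))
            )
            rows.append(
                (cond, reference_gene, rep, ref_base + rng.normal(0.0, params.replicate_sd))
            )
    import pandas as pd

    frame = pd.DataFrame(rows, columns=["condition", "gene", "replicate", "cq"])
    return QpcrPlate(
        frame,
        reference_gene=reference_gene,
        calibrator_condition=calibrator_condition,
    )
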