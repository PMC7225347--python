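import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aequocal import (
    AequorinParams,
    CalibrationConstants,
    allen_calibrate,
    average_traces,
    calibrate,
    estimate_fractional_luminescence,
    occupancy_fraction,
    simulate_photon_trace,
)
from aequocal.protocol import PerfusionProtocol
from aequocal.synthetic import expected_photon_counts
from aequocal.traces import (
    INVALID_BELOW_DOMAIN,
    CalciumTrace,
    FractionalTrace,
    PhotonTrace,
)


def _fractional_from_values(values, protocol=None):
    values = np.asarray(values, dtype=float)
    if protocol is None:
        protocol = PerfusionProtocol.from_durations()
    n = len(protocol.time_grid())
    full = np.zeros(n)
    full[: values.size] = values
    return FractionalTrace(
        time_s=protocol.time_grid(),
        l_over_lmax=full,
        valid=np.ones(n, dtype=bool),
        invalid_reason=np.full(n, "", dtype=object),
        protocol=protocol,
    )


# ---------------------------------------------------------------------------
# fractional luminescence
# ---------------------------------------------------------------------------

def test_constant_counts_remaining_sum_identity(constants):
    """Constant counts c over n bins: L/Lmax at bin i equals 1/(n-i)."""
    protocol = PerfusionProtocol.from_durations(10, 10, 10, 60, 10)
    n = len(protocol.time_grid())
    trace = PhotonTrace(protocol.time_grid(), np.full(n, 50), protocol)
    frac = estimate_fractional_luminescence(
        trace, CalibrationConstants(lmax_floor_counts=0.0)
    )
    for i in (0, 10, n - 2):
        assert frac.l_over_lmax[i] == pytest.approx(1.0 / (n - i))


def test_record_truncated_before_discharge_rejected():
    # a record without a discharge segment cannot define Lmax; the protocol
    # type enforces the presence of the discharge segment at construction
    protocol = PerfusionProtocol.from_durations()
    with pytest.raises(ValueError):
        PerfusionProtocol(protocol.segments[:-1])


def test_all_zero_record_rejected(constants):
    protocol = PerfusionProtocol.from_durations(10, 10, 10, 60, 10)
    n = len(protocol.time_grid())
    trace = PhotonTrace(protocol.time_grid(), np.zeros(n, dtype=int), protocol)
    with pytest.raises(ValueError, match="all-zero"):
        estimate_fractional_luminescence(trace, constants)


def test_fractional_luminescence_tracks_occupancy(preset_truths, constants):
    """Monte-Carlo: estimated L/Lmax matches the simulator's occupancy factor."""
    _, _, truth = preset_truths["wild_type_biphasic"]
    aeq = AequorinParams(initial_quanta=1e8)
    trace = simulate_photon_trace(truth, aeq, seed=11)
    frac = estimate_fractional_luminescence(trace, constants)
    truth_f = occupancy_fraction(truth.ca_molar, constants.k_r, constants.k_tr)
    err = np.abs(frac.l_over_lmax - truth_f)[frac.valid]
    assert err.mean() < 0.01


def test_background_correction_clamps_at_zero():
    protocol = PerfusionProtocol.from_durations(10, 10, 10, 60, 10)
    n = len(protocol.time_grid())
    counts = np.full(n, 5)
    counts[-10:] = 1000  # discharge burst keeps the record non-zero
    trace = PhotonTrace(protocol.time_grid(), counts, protocol)
    frac = estimate_fractional_luminescence(
        trace, CalibrationConstants(background_rate=10.0, lmax_floor_counts=0.0)
    )
    assert np.all(frac.l_over_lmax[:10] == 0.0)


# ---------------------------------------------------------------------------
# occupancy-model inversion
# ---------------------------------------------------------------------------

def test_domain_boundary_maps_to_zero(constants):
    frac = _fractional_from_values([constants.f_floor**3])
    ca = allen_calibrate(frac, constants)
    assert ca.ca_molar[0] == 0.0
    assert not ca.valid[0]
    assert ca.invalid_reason[0] == INVALID_BELOW_DOMAIN


def test_micromolar_scale_example(constants):
    """L/Lmax = 1e-6 (f = 0.01) inverts to ~29.3 nM and forward-recovers."""
    frac = _fractional_from_values([1e-6])
    ca = allen_calibrate(frac, constants)
    expected = (0.01 * 121.0 - 1.0) / (7.23e6 * 0.99)
    assert ca.ca_molar[0] == pytest.approx(expected, rel=1e-12)
    assert occupancy_fraction(ca.ca_molar[0]) == pytest.approx(1e-6, rel=1e-9)


def test_forward_inverse_round_trip(constants):
    ca_grid = np.logspace(-8, -4, 200)
    frac = _fractional_from_values(occupancy_fraction(ca_grid))
    recovered = allen_calibrate(frac, constants).ca_molar[: ca_grid.size]
    assert np.max(np.abs(recovered / ca_grid - 1.0)) < 1e-9


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    f1=st.floats(min_value=0.009, max_value=0.95),
    df=st.floats(min_value=1e-6, max_value=0.04),
    k_tr=st.floats(min_value=10.0, max_value=500.0),
)
def test_calibration_strictly_increasing_in_f(f1, df, k_tr):
    constants = CalibrationConstants(k_tr=k_tr)
    lo = max(f1, constants.f_floor + 1e-9)
    hi = min(lo + df, 0.999)
    frac = _fractional_from_values([lo**3, hi**3])
    ca = allen_calibrate(frac, constants)
    if hi > lo:
        assert ca.ca_molar[1] > ca.ca_molar[0]


def test_invalid_constants_rejected():
    with pytest.raises(ValueError):
        CalibrationConstants(k_r=-1.0)
    with pytest.raises(ValueError):
        CalibrationConstants(k_tr=0.0)


# ---------------------------------------------------------------------------
# end-to-end recovery and invariances
# ---------------------------------------------------------------------------

def test_end_to_end_recovery_all_presets(preset_truths, constants):
    """Simulate -> calibrate recovers ground truth within 10% wherever
    Ca >= 50 nM, at a generous photon budget."""
    aeq = AequorinParams(initial_quanta=1e10)
    for name, (_, _, truth) in preset_truths.items():
        trace = simulate_photon_trace(truth, aeq, seed=5)
        recovered = calibrate(trace, constants)
        mask = recovered.valid & (truth.ca_molar >= 5e-8)
        rel = np.abs(recovered.ca_molar[mask] / truth.ca_molar[mask] - 1.0)
        assert rel.max() < 0.10, name


def test_lambda_sat_invariance(preset_truths):
    """Doubling lambda_sat in simulator AND calibrator leaves Ca unchanged."""
    _, _, truth = preset_truths["alpha_syn_monophasic"]
    recs = []
    for lam, quanta in ((1.0, 2e9), (2.0, 1e9)):
        aeq = AequorinParams(initial_quanta=quanta, lambda_sat=lam)
        cc = CalibrationConstants(lambda_sat=lam)
        recs.append(calibrate(simulate_photon_trace(truth, aeq, seed=3), cc))
    both = recs[0].valid & recs[1].valid & (truth.ca_molar >= 5e-8)
    rel = np.abs(recs[0].ca_molar[both] / recs[1].ca_molar[both] - 1.0)
    assert np.median(rel) < 0.01


def test_detection_efficiency_cancels_in_expectation(preset_truths, constants):
    """Halving detection efficiency leaves expected L/Lmax unchanged."""
    _, _, truth = preset_truths["wild_type_biphasic"]
    means = []
    for eff in (1.0, 0.5):
        aeq = AequorinParams(initial_quanta=2e8, detection_efficiency=eff)
        vals = []
        for seed in range(20):
            trace = simulate_photon_trace(truth, aeq, seed=100 + seed)
            frac = estimate_fractional_luminescence(trace, constants)
            vals.append(frac.l_over_lmax[frac.valid])
        means.append(np.mean(vals, axis=0))
    n = min(means[0].size, means[1].size)
    diff = np.abs(means[0][:n] - means[1][:n])
    assert diff.mean() < 1e-4


# ---------------------------------------------------------------------------
# replicate averaging
# ---------------------------------------------------------------------------

def _ca_trace(protocol, values, valid=None):
    return CalciumTrace(
        time_s=protocol.time_grid(),
        ca_molar=values,
        protocol=protocol,
        valid=valid,
    )


def test_average_single_trace_identity(protocol):
    values = np.full(len(protocol.time_grid()), 2e-7)
    avg = average_traces([_ca_trace(protocol, values)])
    assert np.allclose(avg.mean_ca, values)
    assert np.all(avg.sem_ca == 0.0)
    assert avg.n == 1


def test_average_two_point_case(protocol):
    n = len(protocol.time_grid())
    x, eps = 2e-7, 1e-8
    avg = average_traces(
        [_ca_trace(protocol, np.full(n, x)), _ca_trace(protocol, np.full(n, x + 2 * eps))]
    )
    assert np.allclose(avg.mean_ca, x + eps)
    assert np.allclose(avg.sem_ca, eps)
    assert avg.n == 2


def test_average_mismatched_grids_rejected(protocol):
    short = PerfusionProtocol.from_durations(permeabilized_s=300.0)
    a = _ca_trace(protocol, np.full(len(protocol.time_grid()), 1e-7))
    b = _ca_trace(short, np.full(len(short.time_grid()), 1e-7))
    with pytest.raises(ValueError, match="grid"):
        average_traces([a, b])


def test_sem_band_covers_ground_truth(preset_truths, constants):
    """24 simulated replicates: mean +/- ~2 SEM brackets the truth at >=90%
    of valid bins."""
    _, _, truth = preset_truths["wild_type_biphasic"]
    aeq = AequorinParams(initial_quanta=1e8)
    traces = [
        calibrate(simulate_photon_trace(truth, aeq, seed=200 + i), constants)
        for i in range(24)
    ]
    avg = average_traces(traces)
    ok = np.isfinite(avg.mean_ca) & (avg.sem_ca > 0)
    lo = avg.mean_ca[ok] - 2.1 * avg.sem_ca[ok]
    hi = avg.mean_ca[ok] + 2.1 * avg.sem_ca[ok]
    inside = (truth.ca_molar[ok] >= lo) & (truth.ca_molar[ok] <= hi)
    assert inside.mean() >= 0.90
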