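import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aequocal import (
    AequorinParams,
    GrowthModelParams,
    PerfusionProtocol,
    QpcrSimParams,
    ReleaseComponent,
    generate_ca_trajectory,
    occupancy_fraction,
    preset,
    rise_tau_for_peak,
    simulate_growth,
    simulate_photon_trace,
    simulate_qpcr,
)
from aequocal.synthetic import (
    ProtocolMismatchError,
    ReleaseModelParams,
    expected_photon_counts,
)

UM = 1e-6


# ---------------------------------------------------------------------------
# Ca2+ trajectory generator
# ---------------------------------------------------------------------------

def test_zero_amplitude_trace_is_flat_before_discharge(protocol):
    params = ReleaseModelParams(
        baseline_ca=0.1 * UM,
        external_ca_plateau=0.1 * UM,
        rest_ca=0.1 * UM,
        components=(),
    )
    trace = generate_ca_trajectory(protocol, params)
    before_discharge = ~protocol.mask("discharge")
    assert np.allclose(trace.ca_molar[before_discharge], 0.1 * UM)


def test_single_component_peaks_at_configured_time(protocol):
    comp = ReleaseComponent.from_peak(1.0 * UM, 50.0, 60.0, onset_power=4.0)
    params = ReleaseModelParams(rest_ca=0.0, components=(comp,))
    trace = generate_ca_trajectory(protocol, params)
    perm = protocol.mask("permeabilized")
    t_perm = trace.time_s[perm] - protocol.segment("permeabilized").start_s
    t_max = t_perm[np.argmax(trace.ca_molar[perm])]
    assert abs(t_max - 50.0) <= protocol.bin_width_s
    assert trace.ca_molar[perm].max() == pytest.approx(1.0 * UM, rel=1e-6)


def test_two_components_max_in_second_peak_region(protocol):
    comps = (
        ReleaseComponent.from_peak(1.0 * UM, 50.0, 40.0, onset_power=8.0),
        ReleaseComponent.from_peak(2.0 * UM, 140.0, 150.0, onset_power=40.0),
    )
    params = ReleaseModelParams(rest_ca=0.0, components=comps)
    trace = generate_ca_trajectory(protocol, params)
    perm = protocol.mask("permeabilized")
    t_perm = trace.time_s[perm] - protocol.segment("permeabilized").start_s
    t_max = t_perm[np.argmax(trace.ca_molar[perm])]
    assert 100.0 < t_max < 180.0
    assert trace.ca_molar[perm].max() > 2.0 * UM


def test_component_beyond_permeabilized_segment_rejected():
    protocol = PerfusionProtocol.from_durations(permeabilized_s=100.0)
    comp = ReleaseComponent.from_peak(1.0 * UM, 140.0, 150.0, onset_power=40.0)
    with pytest.raises(ProtocolMismatchError):
        generate_ca_trajectory(protocol, ReleaseModelParams(components=(comp,)))


def test_pulse_peak_time_solver_round_trips():
    for decay, ttp, m in [(60.0, 50.0, 4.0), (150.0, 140.0, 40.0), (90.0, 75.0, 8.0)]:
        rise = rise_tau_for_peak(decay, ttp, m)
        comp = ReleaseComponent(1.0, ttp, rise, decay, m)
        t = np.linspace(0, 600, 60001)
        g = comp.waveform(t)
        assert abs(t[np.argmax(g)] - ttp) < 0.05
        assert g.max() == pytest.approx(1.0, rel=1e-9)


def test_inconsistent_time_to_peak_rejected():
    with pytest.raises(ValueError, match="inconsistent"):
        ReleaseComponent(1.0, 50.0, rise_tau_s=5.0, decay_tau_s=60.0, onset_power=2.0)


# ---------------------------------------------------------------------------
# aequorin photon counting
# ---------------------------------------------------------------------------

@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    ca=st.floats(min_value=0.0, max_value=1e-2),
    k_tr=st.floats(min_value=1.0, max_value=1e4),
)
def test_occupancy_factor_bounded(ca, k_tr):
    f = occupancy_fraction(ca, k_r=7.23e6, k_tr=k_tr)
    lower = (1.0 / (1.0 + k_tr)) ** 3
    assert lower <= f < 1.0
    # strictly increasing
    assert occupancy_fraction(ca + 1e-9, k_r=7.23e6, k_tr=k_tr) > f


def test_quanta_conservation(preset_truths):
    """Over a record run to exhaustion the expected counts sum to eff*N0."""
    _, _, truth = preset_truths["wild_type_biphasic"]
    for eff in (1.0, 0.5):
        aeq = AequorinParams(initial_quanta=1e8, detection_efficiency=eff)
        expected = expected_photon_counts(truth, aeq)
        assert expected.sum() == pytest.approx(eff * 1e8, rel=1e-6)


def test_saturating_discharge_exhausts_quanta_within_5s(preset_truths):
    proto, _, truth = preset_truths["wild_type_biphasic"]
    aeq = AequorinParams(initial_quanta=1e8, lambda_sat=1.0)
    expected = expected_photon_counts(truth, aeq)
    onset = proto.mask("discharge")
    i0 = np.nonzero(onset)[0][0]
    remaining_at_onset = 1e8 - expected[:i0].sum()
    emitted_5s = expected[i0 : i0 + 5].sum()
    # occupancy at 10 mM Ca is ~0.995, so >=99% of 1 - exp(-5)
    assert emitted_5s / remaining_at_onset >= 0.99 * (1 - np.exp(-5))


def test_seeded_reproducibility(preset_truths, aequorin):
    _, _, truth = preset_truths["alpha_syn_monophasic"]
    a = simulate_photon_trace(truth, aequorin, seed=42)
    b = simulate_photon_trace(truth, aequorin, seed=42)
    c = simulate_photon_trace(truth, aequorin, seed=43)
    assert np.array_equal(a.counts, b.counts)
    assert not np.array_equal(a.counts, c.counts)


def test_seed_is_mandatory(preset_truths, aequorin):
    _, _, truth = preset_truths["alpha_syn_monophasic"]
    with pytest.raises(ValueError, match="seed"):
        simulate_photon_trace(truth, aequorin)


def test_non_finite_ca_rejected(protocol, aequorin):
    from aequocal.traces import CalciumTrace

    t = protocol.time_grid()
    ca = np.full(t.shape, 1e-7)
    ca[5] = np.nan
    trace = CalciumTrace(time_s=t, ca_molar=ca, protocol=protocol,
                         valid=np.isfinite(ca))
    with pytest.raises(ValueError, match="non-finite"):
        simulate_photon_trace(trace, aequorin, seed=1)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def test_wild_type_preset_is_biphasic():
    _, params = preset("wild_type_biphasic")
    assert len(params.components) == 2


def test_alpha_syn_preset_has_elevated_rest():
    _, wt = preset("wild_type_biphasic")
    _, syn = preset("alpha_syn_monophasic")
    assert syn.rest_ca > wt.rest_ca
    assert len(syn.components) == 1


def test_pmc1_preset_is_fast_component_only():
    _, wt = preset("wild_type_biphasic")
    _, pmc1 = preset("pmc1_null_fast_only")
    assert len(pmc1.components) == 1
    fast_ttp = min(c.time_to_peak_s for c in wt.components)
    assert pmc1.components[0].time_to_peak_s == pytest.approx(fast_ttp)


def test_unknown_preset_lists_valid_names():
    with pytest.raises(ValueError, match="wild_type_biphasic"):
        preset("nonexistent")


# ---------------------------------------------------------------------------
# growth and qPCR simulators
# ---------------------------------------------------------------------------

def test_noiseless_logistic_midpoint_and_monotonicity():
    params = GrowthModelParams(od_floor=0.0, od_max=1.0, midpoint_h=30.0,
                               noise_sd=0.0, sample_interval_h=0.5)
    curve = simulate_growth(params, seed=1, n_replicates=1)
    od_at_mid = curve.od600[np.isclose(curve.time_h, 30.0)]
    assert od_at_mid == pytest.approx(0.5)
    assert np.all(np.diff(curve.od600) > 0)


def test_growth_seeded_reproducibility():
    params = GrowthModelParams(noise_sd=0.02)
    a = simulate_growth(params, seed=7)
    b = simulate_growth(params, seed=7)
    assert np.array_equal(a.od600, b.od600)


def test_growth_invalid_params_rejected():
    with pytest.raises(ValueError):
        GrowthModelParams(noise_sd=-0.1)
    with pytest.raises(ValueError):
        GrowthModelParams(od_floor=1.0, od_max=0.5)
    with pytest.raises(ValueError, match="seed"):
        simulate_growth(GrowthModelParams())


def test_qpcr_null_ratio_gives_equal_cq():
    params = QpcrSimParams(true_ratio=1.0, replicate_sd=0.0)
    plate = simulate_qpcr(params, seed=1)
    for gene in ("PMC1", "ACT1"):
        control = plate.cq_values("control", gene)
        treated = plate.cq_values("treated", gene)
        assert np.allclose(control, treated)


def test_qpcr_doubling_shift_is_one_cycle():
    params = QpcrSimParams(true_ratio=2.0, efficiency_target=2.0, replicate_sd=0.0)
    plate = simulate_qpcr(params, seed=1)
    dcq = plate.cq_values("control", "PMC1").mean() - plate.cq_values("treated", "PMC1").mean()
    assert dcq == pytest.approx(1.0, abs=1e-12)


def test_qpcr_invalid_efficiency_rejected():
    with pytest.raises(ValueError):
        QpcrSimParams(efficiency_target=1.0)
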