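import numpy as np
import pytest

import spnmorph as sp
from spnmorph.cable import (
    PASSIVE_PRESETS,
    CurrentStep,
    PassiveParams,
    Synapse,
    build_cable_model,
    clustered_drive,
    cylinder_model,
    epsp_attenuation,
    glutamate_synapse,
    isopotential_model,
    measure_tau,
    rescale_species,
    simulate,
    space_constant,
)


def longest_terminal(recon):
    segs = sp.partition_segments(recon)
    terms = [s for s in segs if s.is_terminal]
    return max(terms, key=lambda s: s.length).index


# ---------------------------------------------------------------------------
# space constant and electrotonic lengths


def test_space_constant_check_values():
    # λ = √(R_m·d/(4·R_a)): d=1 μm, R_m=6000 Ω·cm², R_a=150 Ω·cm → 316.23 μm
    assert space_constant(1.0, 6000.0, 150.0) == pytest.approx(316.23, rel=1e-4)
    assert space_constant(1.0, 8000.0, 150.0) == pytest.approx(365.15, rel=1e-4)


def test_space_constant_sqrt_diameter_scaling():
    lam1 = space_constant(1.0, 8000.0, 150.0)
    lam4 = space_constant(4.0, 8000.0, 150.0)
    assert lam4 == pytest.approx(2.0 * lam1, rel=1e-12)
    with pytest.raises(ValueError):
        space_constant(0.0, 8000.0, 150.0)


def test_electrotonic_lengths_straight(straight):
    out = sp.electrotonic_lengths(straight, PASSIVE_PRESETS["mouse"])
    assert len(out) == 1
    s = out[0]
    assert s.L == pytest.approx(s.length / s.lam)
    assert s.lam == pytest.approx(space_constant(s.diameter, 8000.0, 150.0))


# ---------------------------------------------------------------------------
# analytic oracles


def test_isopotential_tau_equals_rm_cm():
    passive = PassiveParams(r_m=10000.0)            # τ = 10000·1e-6·1e3 = 10 ms
    model = isopotential_model(10.0, passive)
    tau = measure_tau(model)
    assert tau == pytest.approx(10.0, rel=0.01)


def test_isopotential_input_resistance():
    passive = PassiveParams(r_m=10000.0)
    r_um = 10.0
    model = isopotential_model(r_um, passive)
    amp = 0.01  # nA
    res = simulate(model, currents=[CurrentStep(0, 0.0, 300.0, amp)],
                   dt=0.05, t_stop=200.0, probes=[0])
    v_ss = res.probe(0)[-1] - passive.e_leak
    area_cm2 = 4 * np.pi * r_um ** 2 * 1e-8
    r_in_Mohm = passive.r_m / area_cm2 * 1e-6
    assert v_ss == pytest.approx(amp * r_in_Mohm, rel=0.005)


def test_steady_state_matches_cosh_profile():
    # sealed finite cable, current at one end:
    # V(x)/V(L) with x from far end follows cosh(x/λ)/cosh(L/λ)
    passive = PassiveParams(r_m=8000.0)
    L, d = 300.0, 1.0
    lam = space_constant(d, passive.r_m, passive.r_a)
    model = cylinder_model(L, d, passive, n_comp=300)
    res = simulate(model, currents=[CurrentStep(0, 0.0, 1e9, 0.05)],
                   dt=0.05, t_stop=400.0, probes=list(range(model.n_comp)))
    v = res.v[:, -1] - passive.e_leak
    x_from_far = L - model.x_mid_um
    expect = np.cosh(x_from_far / lam) / np.cosh(L / lam)
    np.testing.assert_allclose(v / v[0], expect / expect[0], rtol=0.02)


def test_zero_stimulus_fixed_point():
    model = cylinder_model(200.0, 1.0, PASSIVE_PRESETS["mouse"], n_comp=50)
    res = simulate(model, dt=0.1, t_stop=1000.0, probes=[0, 25, 49])
    assert np.max(np.abs(res.v - model.passive.e_leak)) < 1e-9


def test_tau_invariant_under_spine_correction():
    passive = PassiveParams(r_m=10000.0)
    plain = cylinder_model(300.0, 1.0, passive, n_comp=100)
    folded = cylinder_model(300.0, 1.0, passive, n_comp=100,
                            f_correction=lambda x: np.full_like(x, 2.0))
    t1 = measure_tau(plain, comp=0)
    t2 = measure_tau(folded, comp=0)
    assert t2 == pytest.approx(t1, rel=0.01)


def test_dt_halving_convergence():
    model = cylinder_model(200.0, 1.0, PASSIVE_PRESETS["mouse"], n_comp=100)
    syn = glutamate_synapse(model.n_comp - 1, [5.0])
    peaks = []
    for dt in (0.05, 0.025):
        res = simulate(model, synapses=[syn], dt=dt, t_stop=80.0, probes=[0])
        peaks.append((res.probe(0) - model.passive.e_leak).max())
    assert abs(peaks[1] - peaks[0]) / peaks[1] < 0.005


# ---------------------------------------------------------------------------
# model construction


def test_compartment_sizes_respect_rule(mouse_recon):
    model = build_cable_model(mouse_recon, PASSIVE_PRESETS["mouse"])
    dend = ~model.is_soma
    lam = np.array([space_constant(d, 8000.0, 150.0)
                    for d in model.diam_um[dend]])
    assert np.all(model.length_um[dend] <= np.minimum(0.1 * lam, 10.0) + 1e-9)
    assert model.is_soma.sum() == 1


def test_f_correction_scales_membrane_but_not_axial(mouse_recon):
    base = build_cable_model(mouse_recon, PASSIVE_PRESETS["mouse"])
    fold = build_cable_model(mouse_recon, PASSIVE_PRESETS["mouse"],
                             f_correction=lambda x: np.full_like(x, 2.0))
    dend = ~base.is_soma
    np.testing.assert_allclose(fold.c_nF[dend], 2.0 * base.c_nF[dend])
    np.testing.assert_allclose(fold.g_leak_uS[dend], 2.0 * base.g_leak_uS[dend])
    np.testing.assert_allclose(fold.g_axial_uS, base.g_axial_uS)
    ident = build_cable_model(mouse_recon, PASSIVE_PRESETS["mouse"],
                              f_correction=lambda x: np.ones_like(x))
    np.testing.assert_allclose(ident.c_nF, base.c_nF)


def test_unstandardised_reconstruction_rejected():
    recon = sp.straight_dendrite(100.0, 1.0)
    recon.xyz = recon.xyz + np.array([50.0, 0.0, 0.0])  # soma off origin
    assert not recon.is_standardized
    with pytest.raises(ValueError):
        build_cable_model(recon, PASSIVE_PRESETS["mouse"])


# ---------------------------------------------------------------------------
# synapses


def test_mg_block_range_and_monotonicity():
    syn = Synapse(comp=0, onsets=[5.0])
    vs = np.linspace(-90.0, 40.0, 60)
    blocks = np.array([syn.mg_block(v) for v in vs])
    assert np.all(blocks > 0) and np.all(blocks <= 1)
    assert np.all(np.diff(blocks) > 0)
    assert syn.mg_block(0.0) == pytest.approx(1 / (1 + 1 / 3.57))


def test_negative_conductance_rejected():
    with pytest.raises(ValueError):
        Synapse(comp=0, onsets=[5.0], g_ampa=-0.1)


def test_epsp_attenuates_towards_soma(mouse_recon):
    model = build_cable_model(mouse_recon, PASSIVE_PRESETS["mouse"])
    prof = epsp_attenuation(model, longest_terminal(mouse_recon))
    # probe order runs tip (synapse site) → segment base
    assert np.all(np.diff(prof.amplitudes) < 0)
    assert prof.soma_amplitude < prof.amplitudes[-1]
    assert prof.soma_latency > prof.latencies[0]


def test_clustered_local_exceeds_soma(mouse_recon):
    model = build_cable_model(mouse_recon, PASSIVE_PRESETS["mouse"])
    res = clustered_drive(model, longest_terminal(mouse_recon), t_stop=300.0)
    assert res.local_peak_mV > res.soma_peak_mV
    assert res.plateau_duration_ms > 0


def test_nmda_block_shortens_mouse_plateau(mouse_recon):
    model = build_cable_model(mouse_recon, PASSIVE_PRESETS["mouse"])
    term = longest_terminal(mouse_recon)
    intact = clustered_drive(model, term, nmda_on=True, t_stop=300.0)
    blocked = clustered_drive(model, term, nmda_on=False, t_stop=300.0)
    assert blocked.plateau_duration_ms < intact.plateau_duration_ms
    assert blocked.local_peak_mV < intact.local_peak_mV


def test_distributed_drive_monotone_in_rate(straight):
    model = build_cable_model(straight, PASSIVE_PRESETS["mouse"])
    depol = [sp.distributed_drive(model, 0, rate_hz=r, t_stop=600.0,
                                  seed=3).mean_soma_mV
             for r in (2.0, 10.0, 40.0)]
    assert depol[0] < depol[1] < depol[2]


# ---------------------------------------------------------------------------
# species rescaling


def test_rescale_identity(mouse_recon):
    out = rescale_species(mouse_recon, 1.0, 1.0)
    np.testing.assert_allclose(out.xyz, mouse_recon.xyz)
    np.testing.assert_allclose(out.radius, mouse_recon.radius)


def test_rescale_round_trip_diameters(mouse_recon):
    # mouse→human→mouse diameter factors 1.7·0.6 = 1.02: 2% residual inflation
    there = rescale_species(mouse_recon, 1.7, 2.0)
    back = rescale_species(there, 0.6, 0.5)
    dend = mouse_recon.dendrite_mask
    np.testing.assert_allclose(back.radius[dend],
                               1.02 * mouse_recon.radius[dend], rtol=1e-9)


def test_rescale_stretches_terminals_only(mouse_recon):
    out = rescale_species(mouse_recon, 1.0, 2.0)
    segs = sp.partition_segments(mouse_recon)
    segs_out = sp.partition_segments(out)
    for a, b in zip(segs, segs_out):
        factor = b.length / a.length
        assert factor == pytest.approx(2.0 if a.is_terminal else 1.0, rel=1e-9)


def test_rescale_rejects_nonpositive(mouse_recon):
    with pytest.raises(ValueError):
        rescale_species(mouse_recon, 0.0, 1.0)
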