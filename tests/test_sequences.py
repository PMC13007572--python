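"""Experiment assemblies: transfers, selective filter, R1/R1rho/nOe/zz."""
import numpy as np
import pytest
from scipy.linalg import expm

from sniper_nmr import (
    ExchangeModel, RfField, SequenceTiming, SpinLockParams, SpinSystem,
    cssf_filter, fit_monoexp, haha_transfer, make_half_gauss,
    response_profile, rsfpt_transfer, run_noe_experiment, run_r1_experiment,
    run_r1rho_experiment, run_zz_exchange,
)
from sniper_nmr.sequences import (
    DecayCurve, TimingWarning, optimal_transfer_duration, sniper_signal,
    transfer_signal,
)

import oracle

J = 92.0
MATCHED = J / 2.0


@pytest.fixture(scope="module")
def haha_optimum(plain_system=None):
    sys_ = SpinSystem(J_NH=J)
    return optimal_transfer_duration(sys_, MATCHED)


# ---------------------------------------------------------------------------
# transfers

def test_haha_matched_transfer_near_complete(haha_optimum):
    sys_ = SpinSystem(J_NH=J)
    assert haha_transfer(sys_, MATCHED, haha_optimum) >= 0.95


def test_haha_zero_amplitude_no_transfer(haha_optimum):
    assert haha_transfer(SpinSystem(J_NH=J), 0.0, haha_optimum) == \
        pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError):
        haha_transfer(SpinSystem(J_NH=J), MATCHED, 0.0)


def test_haha_selectivity_at_45hz(haha_optimum):
    """45 Hz off-resonance the matched transfer drops below half of the
    on-resonance efficiency."""
    on = haha_transfer(SpinSystem(J_NH=J), MATCHED, haha_optimum)
    off = haha_transfer(SpinSystem(J_NH=J, offset_N=45.0), MATCHED,
                        haha_optimum)
    assert abs(off) < 0.5 * on


def test_rsfpt_matches_haha_efficiency(haha_optimum):
    sys_ = SpinSystem(J_NH=J)
    e_haha = haha_transfer(sys_, MATCHED, haha_optimum)
    e_rsfpt = rsfpt_transfer(sys_, MATCHED)
    assert e_rsfpt >= 0.9 * e_haha
    assert rsfpt_transfer(sys_, 0.0) == pytest.approx(0.0, abs=1e-9)


def test_rsfpt_offset_profile_tens_of_hz():
    grid = np.linspace(-100, 100, 81)
    prof = response_profile(transfer_signal(MATCHED, transfer="rsfpt"),
                            SpinSystem(J_NH=J), grid)
    assert 10.0 < prof.fwhm < 100.0


# ---------------------------------------------------------------------------
# chemical-shift-selective filter

def test_cssf_null_at_quarter_zeta_inverse():
    zeta = 0.004
    sys_ = SpinSystem(J_NH=J, offset_N=1.0 / (4 * zeta))
    assert cssf_filter(sys_, "ideal", zeta) == pytest.approx(0.0, abs=1e-10)


def test_cssf_zeta_zero_passes_everything():
    sys_ = SpinSystem(J_NH=J, offset_N=33.0)
    assert cssf_filter(sys_, "ideal", 0.0) == pytest.approx(1.0, abs=1e-10)
    with pytest.raises(ValueError):
        cssf_filter(sys_, "ideal", -0.001)


@pytest.mark.parametrize("offset", [0.0, 11.0, 25.0, -40.0])
def test_cssf_cosine_law(offset):
    """Ideal pulses and ideal decoupling reproduce cos(2 pi dnu zeta)
    exactly; with the proton coupling decoupled by finite-power CW
    irradiation a ~1e-8 residual remains (a representable decoupling
    imperfection)."""
    zeta = 0.003
    expected = np.cos(2 * np.pi * offset * zeta)
    exact = cssf_filter(SpinSystem(J_NH=0.0, offset_N=offset), "ideal",
                        zeta, decoupling_amplitude=0.0)
    assert exact == pytest.approx(expected, abs=1e-12)
    with_cw = cssf_filter(SpinSystem(J_NH=J, offset_N=offset), "ideal",
                          zeta)
    assert with_cw == pytest.approx(expected, abs=1e-6)


def test_cssf_with_half_gauss_matches_oracle(relaxing_system):
    """Shaped-excitation filter retention agrees with the brute-force
    Hilbert-space integrator."""
    hg = make_half_gauss(0.04, n_slices=48)
    zeta = 0.002
    sys_ = relaxing_system.replace(offset_N=9.0, offset_H=0.0)
    retained = cssf_filter(sys_, hg, zeta)

    segments = [([RfField("N", hg.peak_amplitude * f, p + 90.0),
                  RfField("H", 2000.0)], hg.dt) for f, p in hg.slices]
    segments.append(([RfField("H", 2000.0)], zeta))
    rho = oracle.matrix_from_coefficients(np.eye(16)[6])
    rho = oracle.integrate(sys_, rho, segments, include_recovery=False)
    c = oracle.coefficients(rho)
    # hard 90(-y) returns the x component to z; purge keeps longitudinal
    assert retained == pytest.approx(c[4], abs=1e-8)


# ---------------------------------------------------------------------------
# R1 experiment

@pytest.mark.parametrize("r1", [0.5, 1.5, 3.0])
def test_r1_rate_recovery_within_2_percent(r1):
    sys_ = SpinSystem(J_NH=J, R1_N=r1, R2_N=max(4.0, 2 * r1), R1_H=1.2,
                      R2_H=8.0)
    timing = SequenceTiming(relax_delays=list(np.linspace(0, 1.5 / r1, 8)))
    curve = run_r1_experiment(sys_, make_half_gauss(0.05, n_slices=96),
                              timing)
    fit = fit_monoexp(curve)
    assert fit.rate == pytest.approx(r1, rel=0.02)


def test_r1_flat_without_relaxation():
    sys_ = SpinSystem(J_NH=J)
    timing = SequenceTiming(relax_delays=[0.0, 0.5, 1.0])
    curve = run_r1_experiment(sys_, "ideal", timing)
    assert np.ptp(curve.intensities) < 1e-9 * abs(curve.intensities[0])


def test_r1_requires_delays(relaxing_system):
    with pytest.raises(ValueError):
        run_r1_experiment(relaxing_system, "ideal",
                          SequenceTiming(relax_delays=None))


def test_golem_suppresses_8hz_contaminant(golem_default):
    """A neighbor 8 Hz away contributes < 5% of the target amplitude to
    the selective experiment's signal."""
    _, shape, _ = golem_default
    sys_t = SpinSystem(J_NH=J, R1_N=1.5, R2_N=6.0, R1_H=1.2, R2_H=8.0)
    signal = sniper_signal(shape)
    target = signal(sys_t)
    contaminant = signal(sys_t.replace(offset_N=8.0))
    assert abs(contaminant) < 0.05 * abs(target)


# ---------------------------------------------------------------------------
# constant-time R1rho

@pytest.mark.parametrize("r2", [2.0, 6.0, 15.0])
def test_r1rho_on_resonance_recovers_r2(r2):
    sys_ = SpinSystem(J_NH=J, R1_N=1.2, R2_N=r2, R1_H=1.2, R2_H=8.0)
    tmax = min(0.25, 2.0 / r2)
    timing = SequenceTiming(relax_delays=list(np.linspace(0, tmax, 8)),
                            ct_relax_time=tmax)
    curve = run_r1rho_experiment(sys_, "ideal", timing,
                                 SpinLockParams(1500.0))
    fit = fit_monoexp(curve)
    assert fit.rate == pytest.approx(r2, rel=0.02)


def test_r1rho_tilted_frame_limit():
    """As the lock moves far off resonance (theta -> 0) the decay rate
    tends to R1."""
    sys_ = SpinSystem(J_NH=J, R1_N=1.2, R2_N=6.0, R1_H=1.2, R2_H=8.0)
    rates = []
    for offset in [0.0, 1500.0, 8000.0]:
        sl = SpinLockParams(1500.0, offset)
        timing = SequenceTiming(relax_delays=list(np.linspace(0, 0.25, 6)),
                                ct_relax_time=0.25)
        fit = fit_monoexp(run_r1rho_experiment(sys_, "ideal", timing, sl))
        th = np.deg2rad(sl.theta)
        expected = sys_.R1_N * np.cos(th) ** 2 + sys_.R2_N * np.sin(th) ** 2
        assert fit.rate == pytest.approx(expected, rel=0.02)
        rates.append(fit.rate)
    assert rates[0] > rates[1] > rates[2]
    assert rates[2] - sys_.R1_N < 0.25 * (sys_.R2_N - sys_.R1_N)


def test_r1rho_alignment_removes_oscillation():
    sys_ = SpinSystem(J_NH=J, R1_N=1.2, R2_N=6.0, R1_H=1.2, R2_H=8.0)
    sl = SpinLockParams(1500.0, 1500.0)       # 45-degree tilt
    timing = SequenceTiming(
        relax_delays=list(np.linspace(0, 0.02, 24)), ct_relax_time=0.02)
    aligned = run_r1rho_experiment(sys_, "ideal", timing, sl, align=True)
    tilted = run_r1rho_experiment(sys_, "ideal", timing, sl, align=False)

    def oscillation(curve):
        fit = fit_monoexp(curve)
        resid = curve.intensities - fit.amplitude * np.exp(
            -fit.rate * curve.delays)
        return np.max(np.abs(resid)) / abs(curve.intensities[0])

    assert oscillation(aligned) < 0.01
    assert oscillation(tilted) > 0.05


def test_r1rho_validation(relaxing_system):
    timing = SequenceTiming(relax_delays=[0.0, 0.1, 0.3],
                            ct_relax_time=0.2)
    with pytest.raises(ValueError):
        run_r1rho_experiment(relaxing_system, "ideal", timing,
                             SpinLockParams(1500.0))
    with pytest.raises(ValueError):
        SpinLockParams(0.0)


# ---------------------------------------------------------------------------
# steady-state nOe

def test_noe_unity_without_cross_relaxation():
    sys_ = SpinSystem(J_NH=J, R1_N=1.5, R2_N=6.0, R1_H=1.2, R2_H=8.0)
    ratio = run_noe_experiment(sys_, None, SequenceTiming(
        noe_saturation_time=6.0))
    assert ratio == pytest.approx(1.0, abs=1e-6)


def test_noe_matches_steady_state_closed_form():
    sys_ = SpinSystem(J_NH=J, R1_N=1.5, R2_N=6.0, R1_H=1.2, R2_H=8.0,
                      sigma_HN=-0.05 * 1.5, gamma_ratio=-9.87)
    ratio = run_noe_experiment(sys_, None, SequenceTiming(
        noe_saturation_time=8.0))
    expected = 1.0 + sys_.gamma_ratio * sys_.sigma_HN / sys_.R1_N
    assert expected == pytest.approx(1.4935)
    assert ratio == pytest.approx(expected, rel=0.01)


def test_noe_short_saturation_warns():
    sys_ = SpinSystem(J_NH=J, R1_N=1.0, R2_N=4.0, R1_H=1.0, R2_H=4.0)
    with pytest.warns(TimingWarning):
        run_noe_experiment(sys_, None, SequenceTiming(
            noe_saturation_time=1.0))


# ---------------------------------------------------------------------------
# zz exchange

def test_zz_no_exchange_no_cross_peaks():
    ex = ExchangeModel.two_site(0.0, 60.0, 0.0)
    sys_ = SpinSystem(J_NH=J, R1_N=1.5, R2_N=6.0, R1_H=1.2, R2_H=8.0)
    out = run_zz_exchange(sys_, ex, None, [0.05, 0.1, 0.2],
                          ideal_preparation=True)
    np.testing.assert_allclose(out[1], 0.0, atol=1e-12)


def test_zz_symmetric_exchange_matches_tanh_law():
    k_ex = 5.0
    ex = ExchangeModel.two_site(0.0, 60.0, k_ex)
    sys_ = SpinSystem(J_NH=J, R1_N=1.5, R2_N=6.0, R1_H=1.2, R2_H=8.0)
    mix = np.array([0.02, 0.05, 0.1, 0.2, 0.4])
    out = run_zz_exchange(sys_, ex, None, mix, ideal_preparation=True)
    np.testing.assert_allclose(out[1] / out[0], np.tanh(k_ex * mix / 2.0),
                               atol=1e-6)


def test_zz_total_longitudinal_decays_at_r1():
    ex = ExchangeModel.two_site(0.0, 60.0, 5.0)
    sys_ = SpinSystem(J_NH=J, R1_N=1.5, R2_N=6.0, R1_H=1.2, R2_H=8.0)
    mix = np.array([0.0, 0.1, 0.3, 0.6])
    out = run_zz_exchange(sys_, ex, None, mix, ideal_preparation=True)
    total = out.sum(axis=0)
    np.testing.assert_allclose(total / total[0],
                               np.exp(-sys_.R1_N * mix), atol=1e-9)


def test_zz_full_preparation_selects_carrier_state():
    """With the selective preparation the carrier state dominates and the
    subsequent mixing follows the two-site kinetic propagator."""
    k_ex = 5.0
    ex = ExchangeModel.two_site(0.0, 120.0, k_ex)
    sys_ = SpinSystem(J_NH=J, R1_N=1.5, R2_N=6.0, R1_H=1.2, R2_H=8.0)
    mix = np.array([0.0, 0.05, 0.15, 0.3])
    out = run_zz_exchange(sys_, ex, None, mix,
                          timing=SequenceTiming(zeta=0.004))
    assert abs(out[1, 0]) < 0.05 * abs(out[0, 0])
    kin = ex.rate_matrix - sys_.R1_N * np.eye(2)
    for m, t in enumerate(mix):
        expected = expm(kin * t) @ out[:, 0]
        np.testing.assert_allclose(out[:, m], expected, atol=1e-6)


def test_zz_warns_when_exchange_not_slow():
    ex = ExchangeModel.two_site(0.0, 10.0, 50.0)
    sys_ = SpinSystem(J_NH=J, R1_N=1.5, R2_N=6.0, R1_H=1.2, R2_H=8.0)
    with pytest.warns(TimingWarning):
        run_zz_exchange(sys_, ex, None, [0.1], ideal_preparation=True)


# ---------------------------------------------------------------------------
# response profiles

def test_profile_on_resonance_normalization(haha_optimum):
    grid = np.linspace(-60, 60, 25)
    prof = response_profile(transfer_signal(MATCHED, haha_optimum),
                            SpinSystem(J_NH=J), grid)
    assert prof.response[np.argmin(np.abs(prof.offsets))] == \
        pytest.approx(1.0, abs=1e-9)


def test_profile_symmetry():
    """The evolution generator maps offset sign flip to rf phase
    conjugation, so a profile mirrors exactly when every slice phase is
    negated; for a symmetric zero-phase shape on an uncoupled spin the
    profile itself is symmetric."""
    from sniper_nmr import excitation_profile
    from sniper_nmr.shapes import Shape

    rng = np.random.default_rng(5)
    slices = np.column_stack([rng.uniform(0.1, 1.0, 40),
                              rng.uniform(-90, 90, 40)])
    shape = Shape(slices, 0.04, 12.0)
    conj = Shape(np.column_stack([slices[:, 0], -slices[:, 1]]),
                 0.04, 12.0)
    grid = np.linspace(-30, 30, 21)
    sys_ = SpinSystem(J_NH=J, R1_N=1.0, R2_N=4.0, R1_H=1.0, R2_H=4.0)
    p1 = excitation_profile(shape, sys_, grid, phase_offset=90.0)
    p2 = excitation_profile(conj, sys_, grid, phase_offset=-90.0)
    np.testing.assert_allclose(p1.response, p2.response[::-1], atol=1e-9)

    hg = make_half_gauss(0.04, n_slices=48)
    prof = excitation_profile(hg, SpinSystem(J_NH=0.0), grid,
                              decoupling_amplitude=0.0)
    assert np.max(np.abs(prof.response - prof.response[::-1])) < 1e-9


def test_full_experiment_transfer_selectivity_35_to_45_hz():
    """The matched-transfer selectivity of the complete experiment
    (forward + readout transfer, hard-pulse filter) lies in the stated
    35-45 Hz window."""
    grid = np.linspace(-60, 60, 121)
    prof = response_profile(sniper_signal("ideal", SequenceTiming(zeta=0.0)),
                            SpinSystem(J_NH=J), grid)
    assert 35.0 <= prof.fwhm <= 45.0


def test_decay_curve_validation():
    with pytest.raises(ValueError):
        DecayCurve([0.1], [1.0])
    with pytest.raises(ValueError):
        DecayCurve([0.1, 0.1], [1.0, 0.9])
    with pytest.raises(ValueError):
        DecayCurve([0.0, 0.1], [1.0])


def test_timing_warnings():
    with pytest.warns(TimingWarning):
        SequenceTiming(zeta=0.008)
    with pytest.warns(TimingWarning):
        SequenceTiming(delta=0.002)
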