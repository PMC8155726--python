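import numpy as np
import pytest
from scipy.signal import lfilter

from pwvest import (CentralHemodynamics, NoiseSpec, apply_signal_noise,
                    compute_zao, ct_decay_time, ct_pulse_pressure_method,
                    solve_hemodynamics, zao_peak_flow, zao_time_derivative_peaks)
from pwvest.solver import Waveform

from conftest import make_inflow, make_tube

FS = 1000.0


def wk2_pressure(q_mls, r, c, fs=FS, beats=60):
    """Periodic steady-state pressure of an exact 2-element Windkessel."""
    dt = 1.0 / fs
    decay = np.exp(-dt / (r * c))
    forcing = r * (1 - decay)
    p0 = q_mls.mean() * r
    for _ in range(beats):
        p, _ = lfilter([forcing], [1.0, -decay], q_mls, zi=np.array([decay * p0]))
        p0 = p[-1]
    return p


def half_sine_flow(t, ts=0.3, qmax=400.0):
    return np.where(t < ts, qmax * np.sin(np.pi * t / ts), 0.0)


def make_central(p, q, notch=None, fs=FS):
    pw = Waveform("aortic_root", "pressure", p, fs, "mmHg")
    qw = Waveform("aortic_root", "flow", q, fs, "mL/s")
    if notch is None:
        i_peak = int(np.argmax(q))
        notch = (i_peak + int(np.argmax(q[i_peak:] <= 0))) / fs
    return CentralHemodynamics(pw, qw, notch_time=notch)


def test_tdp_proportional_waves_exact():
    """If P = Z*Q + const, the derivative-peak ratio returns Z exactly."""
    t = np.arange(0, 0.8, 1 / FS)
    q = half_sine_flow(t)
    z = 0.07
    p = 80.0 + z * q
    h = make_central(p, q)
    assert zao_time_derivative_peaks(h) == pytest.approx(z, rel=1e-9)


def test_tdp_hand_arithmetic():
    assert 800.0 / 14286.0 == pytest.approx(0.056, rel=1e-3)


def test_peak_flow_arithmetic_and_scaling():
    t = np.arange(0, 0.8, 1 / FS)
    q = half_sine_flow(t, qmax=400.0)
    p = np.full_like(t, 78.0)
    p[np.argmax(q)] = 100.4
    h = make_central(p, q)
    assert zao_peak_flow(h) == pytest.approx((100.4 - 78.0) / 400.0, rel=1e-9)
    assert zao_peak_flow(h) == pytest.approx(0.056, rel=1e-3)
    h2 = make_central(p, 2 * q)
    assert zao_peak_flow(h2) == pytest.approx(zao_peak_flow(h) / 2, rel=1e-9)


def test_dtm_exact_monoexponential():
    """P = 120*exp(-t/1.14) in diastole with R = 1 -> C_T = 1.14 (+-0.1%)."""
    t = np.arange(0, 1.0, 1 / FS)
    notch = 0.35
    p = np.where(t < notch, 80 + 120 * np.sin(np.pi * t / (2 * notch)),
                 200.0 * np.exp(-(t - notch) / 1.14))
    p = np.maximum(p, 1.0)
    q = half_sine_flow(t, ts=notch, qmax=500.0)
    q = q * (np.mean(p) / np.mean(q))  # R = mean P / mean Q = 1 exactly
    h = make_central(p, q, notch=notch)
    assert h.peripheral_resistance == pytest.approx(1.0, rel=1e-12)
    assert ct_decay_time(h) == pytest.approx(1.14, rel=1e-3)
    # tau/R scaling: halving mean flow doubles R and halves C
    h2 = make_central(p, 0.5 * q, notch=notch)
    assert ct_decay_time(h2) == pytest.approx(0.57, rel=1e-3)


def test_dtm_rejects_nondecaying_diastole():
    t = np.arange(0, 1.0, 1 / FS)
    p = 80 + 20 * t  # rising pressure
    q = half_sine_flow(t)
    h = make_central(p, q, notch=0.35)
    with pytest.raises(ValueError, match="decay"):
        ct_decay_time(h)


def test_ppm_recovers_windkessel_compliance():
    """Pressure generated by an exact 2-element WK (C = 1.20, R = 1.0) from
    the same flow: PPM returns 1.20 within tolerance."""
    t = np.arange(0, 0.8, 1 / FS)
    q = half_sine_flow(t, qmax=400.0)
    r_true, c_true = 1.0, 1.20
    q = q * 80.0 / q.mean()  # mean flow 80 -> mean pressure 80 -> R = 1
    p = wk2_pressure(q, r_true, c_true)
    h = make_central(p, q)
    assert h.peripheral_resistance == pytest.approx(r_true, rel=1e-6)
    assert ct_pulse_pressure_method(h) == pytest.approx(c_true, abs=2e-4)


def test_ppm_scaling_relations():
    """Windkessel homogeneity: scaling pressure and flow together leaves the
    recovered compliance unchanged; doubling flow alone (which halves the
    measured R) doubles it — dP/dt=(2Q-2P/R)/C traces the (Q, R, C/2) system,
    so matching the same pulse pressure requires twice the compliance."""
    t = np.arange(0, 0.8, 1 / FS)
    q = half_sine_flow(t, qmax=400.0)
    q = q * 80.0 / q.mean()
    p = wk2_pressure(q, 1.0, 1.20)
    c1 = ct_pulse_pressure_method(make_central(p, q))
    c_joint = ct_pulse_pressure_method(make_central(1.3 * p, 1.3 * q))
    assert c_joint == pytest.approx(c1, abs=5e-4)
    c_flow = ct_pulse_pressure_method(make_central(p, 2.0 * q))
    assert c_flow == pytest.approx(2.0 * c1, rel=2e-3)


def test_ppm_invariant_to_bracket():
    t = np.arange(0, 0.8, 1 / FS)
    q = half_sine_flow(t, qmax=400.0)
    q = q * 80.0 / q.mean()
    p = wk2_pressure(q, 1.0, 1.20)
    h = make_central(p, q)
    a = ct_pulse_pressure_method(h, bracket=(0.01, 10.0))
    b = ct_pulse_pressure_method(h, bracket=(0.2, 4.0))
    assert a == pytest.approx(b, abs=2e-4)


def test_dtm_ppm_agree_on_exact_windkessel():
    """Both compliance methods recover C within 1% and agree within 2%."""
    t = np.arange(0, 0.9, 1 / FS)
    q = half_sine_flow(t, ts=0.32, qmax=420.0)
    q = q * 95.0 / q.mean()
    p = wk2_pressure(q, 1.0, 1.3)
    h = make_central(p, q, notch=0.32)
    dtm = ct_decay_time(h)
    ppm = ct_pulse_pressure_method(h)
    assert dtm == pytest.approx(1.3, rel=0.01)
    assert ppm == pytest.approx(1.3, rel=0.01)
    assert dtm == pytest.approx(ppm, rel=0.02)


def test_zao_estimators_on_reflectionless_tube():
    """On a matched tube both early-systolic estimators approximate the
    water-hammer Z_ao within 3% at 1 kHz sampling."""
    tube = make_tube(length=0.8, speed=8.0)
    # small baseline flow keeps diastolic pressure positive on the pure
    # resistor termination while leaving the early-systolic ratios intact
    waves = solve_hemodynamics(tube, make_inflow(offset=5.0),
                               sampling_rate=1000.0,
                               wall_damping=0.0, viscosity=0.0)
    h = CentralHemodynamics.from_waveforms(waves)
    z_ref = compute_zao(tube)
    assert zao_time_derivative_peaks(h) == pytest.approx(z_ref, rel=0.03)
    assert zao_peak_flow(h) == pytest.approx(z_ref, rel=0.03)


def test_apply_signal_noise_identity_and_scaling():
    t = np.arange(0, 0.8, 1 / FS)
    q = half_sine_flow(t)
    p = 80 + 0.07 * q
    h = make_central(p, q)
    same = apply_signal_noise(h, NoiseSpec(0.0, rng_seed=0))
    assert np.array_equal(same.aortic_pressure.samples, p)

    noisy = apply_signal_noise(h, NoiseSpec(0.15, rng_seed=5))
    factor = noisy.aortic_pressure.samples / p
    assert np.allclose(factor, factor[0])  # one factor for the whole signal
    assert 0.85 <= factor[0] <= 1.15
    assert noisy.notch_time == h.notch_time


def test_classical_report_on_cohort(small_cohort_records):
    from pwvest.pipeline import classical_comparison, classical_report
    _, records = small_cohort_records
    est = classical_comparison(records, NoiseSpec(0.15, rng_seed=9))
    rep = classical_report(est)
    assert set(rep["method"]) == {"time-derivative peaks", "peak flow",
                                  "decay time", "pulse pressure"}
    # all four methods produce positively correlated estimates
    assert (rep["r"] > 0.5).all()
    # the decay-time method overestimates C_T on average (positive bias)
    dtm = rep[rep["method"] == "decay time"].iloc[0]
    assert dtm["bias"] > 0
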