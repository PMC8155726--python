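"""Classical comparator estimators of Z_ao and C_T.

Four previously published methods that, unlike the PWV-based regressors,
require the central (aortic) pressure and flow waveforms:

* time-derivative peaks method:  Z_ao = P'_max / Q'_max
* peak flow method:              Z_ao = (P_Qmax - aDBP) / Q_max
* decay time method (DTM):       monoexponential fit of diastolic pressure
  gives the time constant tau = R*C_T, so C_T = tau / R
* pulse pressure method (PPM):   the C of a two-element Windkessel (driven by
  the measured flow, with the measured R) whose periodic steady-state pulse
  pressure matches the measured aortic pulse pressure.

Peripheral resistance R is computed as mean aortic pressure over mean aortic
flow (venous pressure neglected).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .features import NoiseSpec, detect_dicrotic_notch, flow_systole_end
from .solver import Waveform


@dataclass
class CentralHemodynamics:
    """Central (aortic) pressure and flow for one subject.

    Pressure in mmHg, flow in mL/s; `notch_time` delimits systole/diastole
    and `notch_from_flow` flags the fallback to the flow zero crossing when
    no pressure notch was found.
    """

    aortic_pressure: Waveform
    aortic_flow: Waveform
    notch_time: float
    notch_from_flow: bool = False

    def __post_init__(self):
        if float(np.mean(self.aortic_flow.samples)) <= 0:
            raise ValueError("mean aortic flow must be positive")

    @classmethod
    def from_waveforms(cls, waves: dict[str, Waveform]) -> "CentralHemodynamics":
        """Build from a subject waveform dict (pressure:aortic_root, flow:aortic_root)."""
        p = waves["pressure:aortic_root"]
        q = waves["flow:aortic_root"]
        t_notch, found = detect_dicrotic_notch(p)
        if not found:
            t_notch = flow_systole_end(q)
        return cls(aortic_pressure=p, aortic_flow=q, notch_time=t_notch,
                   notch_from_flow=not found)

    @property
    def peripheral_resistance(self) -> float:
        """R = mean aortic pressure / mean aortic flow [mmHg s/mL]."""
        return float(np.mean(self.aortic_pressure.samples)
                     / np.mean(self.aortic_flow.samples))


def zao_time_derivative_peaks(h: CentralHemodynamics) -> float:
    """Z_ao = P'_max / Q'_max [mmHg s/mL], central-difference derivatives."""
    dt_p = 1.0 / h.aortic_pressure.sampling_rate
    dt_q = 1.0 / h.aortic_flow.sampling_rate
    dp_max = float(np.max(np.gradient(h.aortic_pressure.samples, dt_p)))
    dq_max = float(np.max(np.gradient(h.aortic_flow.samples, dt_q)))
    if dq_max <= 0:
        raise ValueError("maximum flow derivative is non-positive")
    if dp_max <= 0:
        raise ValueError("maximum pressure derivative is non-positive")
    return dp_max / dq_max


def zao_peak_flow(h: CentralHemodynamics) -> float:
    """Z_ao = (P at peak flow - aortic DBP) / peak flow [mmHg s/mL]."""
    q = h.aortic_flow.samples
    p = h.aortic_pressure.samples
    i_qmax = int(np.argmax(q))
    q_max = float(q[i_qmax])
    if q_max <= 0:
        raise ValueError("peak flow is non-positive")
    # pressure sample at the instant of peak flow (same time base)
    t_qmax = i_qmax / h.aortic_flow.sampling_rate
    i_p = int(round(t_qmax * h.aortic_pressure.sampling_rate)) % p.size
    adbp = float(np.min(p))
    return (float(p[i_p]) - adbp) / q_max


def ct_decay_time(h: CentralHemodynamics, fit_start: float = 0.1,
                  fit_end: float = 1.0) -> float:
    """C_T by the decay time method [mL/mmHg].

    Log-linear least-squares fit of aortic pressure over a diastolic window
    gives the time constant tau = R*C_T. The window runs from
    notch + fit_start*(diastole duration) to notch + fit_end*(diastole
    duration); the default skips the first 10% of diastole to avoid notch
    transients.
    """
    p = h.aortic_pressure.samples
    fs = h.aortic_pressure.sampling_rate
    period = h.aortic_pressure.period
    diastole = period - h.notch_time
    if diastole <= 0:
        raise ValueError("notch time not inside the beat")
    i0 = int(round((h.notch_time + fit_start * diastole) * fs))
    i1 = int(round((h.notch_time + fit_end * diastole) * fs))
    i1 = min(i1, p.size)
    if i1 - i0 < 4:
        raise ValueError("diastolic fit window too short")
    window = p[i0:i1]
    if np.any(window <= 0):
        raise ValueError("non-positive pressure in diastolic window")
    t = np.arange(i0, i1) / fs
    slope, _ = np.polyfit(t, np.log(window), 1)
    if slope >= 0:
        raise ValueError("diastolic pressure does not decay: tau <= 0")
    tau = -1.0 / slope
    return tau / h.peripheral_resistance


def _windkessel_pp(c: float, r: float, q: np.ndarray, dt: float,
                   max_beats: int = 20, pp_tol: float = 1e-6) -> float:
    """Pulse pressure of a 2-element Windkessel driven by one flow beat.

    Integrates dP/dt = (Q - P/R)/C with an exact exponential step (Q held
    constant over each sample) repeated over beats until the beat-to-beat
    pulse-pressure change falls below `pp_tol` or `max_beats` is reached.
    """
    from scipy.signal import lfilter

    tau = r * c
    decay = np.exp(-dt / tau)
    forcing = r * (1.0 - decay)
    p0 = float(np.mean(q)) * r  # start from the mean-flow equilibrium
    pp_prev = None
    pp = 0.0
    for _ in range(max_beats):
        # exact exponential step p[n] = decay*p[n-1] + forcing*q[n]
        p, zf = lfilter([forcing], [1.0, -decay], q, zi=np.array([decay * p0]))
        pp = float(np.max(p) - np.min(p))
        p0 = float(p[-1])
        if pp_prev is not None and abs(pp - pp_prev) < pp_tol:
            break
        pp_prev = pp
    return pp


def ct_pulse_pressure_method(h: CentralHemodynamics, tolerance: float = 1e-4,
                             max_iter: int = 60,
                             bracket: tuple[float, float] = (0.01, 10.0)) -> float:
    """C_T by the pulse pressure method [mL/mmHg].

    Bisection on the Windkessel compliance C such that the periodic
    steady-state pulse pressure of the two-element Windkessel (driven by the
    measured aortic flow, with the measured R) matches the measured aortic
    pulse pressure. Monotone: larger C gives smaller pulse pressure.
    """
    p = h.aortic_pressure.samples
    pp_measured = float(np.max(p) - np.min(p))
    q = h.aortic_flow.samples
    dt = 1.0 / h.aortic_flow.sampling_rate
    r = h.peripheral_resistance

    c_lo, c_hi = bracket
    f_lo = _windkessel_pp(c_lo, r, q, dt) - pp_measured
    f_hi = _windkessel_pp(c_hi, r, q, dt) - pp_measured
    if f_lo * f_hi > 0:
        raise ValueError(f"no bracketing interval for PPM in {bracket}")
    for _ in range(max_iter):
        c_mid = 0.5 * (c_lo + c_hi)
        if c_hi - c_lo < tolerance:
            return c_mid
        f_mid = _windkessel_pp(c_mid, r, q, dt) - pp_measured
        if f_lo * f_mid <= 0:
            c_hi = c_mid
        else:
            c_lo, f_lo = c_mid, f_mid
    raise RuntimeError(f"PPM bisection did not converge in {max_iter} iterations")


def apply_signal_noise(h: CentralHemodynamics, spec: NoiseSpec) -> CentralHemodynamics:
    """Scale each whole signal (pressure, flow) by an independent (1+e) factor,
    e ~ U[-max_level, +max_level]; the waveform shapes are preserved."""
    rng = np.random.default_rng(spec.rng_seed)
    f_p, f_q = 1.0 + rng.uniform(-spec.max_level, spec.max_level, size=2)
    p = replace(h.aortic_pressure, samples=h.aortic_pressure.samples * f_p)
    q = replace(h.aortic_flow, samples=h.aortic_flow.samples * f_q)
    return CentralHemodynamics(aortic_pressure=p, aortic_flow=q,
                               notch_time=h.notch_time,
                               notch_from_flow=h.notch_from_flow)
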