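"""Frequency-domain transmission-line solver for the arterial tree.

Each segment is a uniform lossy transmission line with (per unit length)
series impedance z = R' + i*omega*L' and shunt admittance y = i*omega*C_A*w:

* L' = rho/A is the blood inertance,
* R' = 8*pi*mu/A^2 is the Poiseuille viscous resistance (mu blood viscosity),
* C_A is the area compliance and w = (1 - i*a)^2 a viscoelastic wall-damping
  factor; for R' = 0 this reduces to the wave number k = (omega/c)(1 - i*a),
  i.e. each harmonic decays by exp(-a*omega*x/c) at unchanged phase velocity.

Per harmonic, input impedances are propagated from the terminal Windkessels
to the root (hyperbolic line transformation); the inflow spectrum then fixes
the root pressure, and forward/backward wave amplitudes are propagated back
down the tree to evaluate pressure at arbitrary positions. The DC (zeroth)
harmonic is solved as a resistive network: segment Poiseuille resistances in
series with the terminal resistances set the mean-pressure gradients and the
flow split.

With viscosity and wall damping set to zero and a matched (reflectionless)
load, the input impedance equals the characteristic impedance rho*c/A
identically at every frequency — the water-hammer relation.

This yields the periodic steady state directly — the linear-network analogue
of the "analytical solution" style of arterial pulse-wave models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree import ArterialTreeModel, CardiacInflow
from .units import BLOOD_DENSITY, m3s_to_mls, pa_to_mmhg

DEFAULT_SAMPLING_RATE = 1000.0
DEFAULT_N_HARMONICS = 40
DEFAULT_WALL_DAMPING = 0.15
DEFAULT_BLOOD_VISCOSITY = 0.02  # Pa s (effective: includes omitted 3-D/viscoelastic losses)


class HemodynamicsError(RuntimeError):
    """Raised when the solve produces a non-physical (non-positive) pressure."""


@dataclass
class Waveform:
    """One period of a uniformly sampled pressure or flow signal."""

    site: str
    kind: str  # 'pressure' | 'flow'
    samples: np.ndarray
    sampling_rate: float
    units: str  # 'mmHg' | 'mL/s'

    def __post_init__(self):
        if self.sampling_rate < 250.0:
            raise ValueError("sampling_rate must be >= 250 Hz")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.kind == "pressure" and np.any(self.samples <= 0):
            raise ValueError(f"non-positive pressure in waveform at {self.site}")

    @property
    def period(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


class _LineParams:
    """Per-segment propagation constant and characteristic impedance.

    Arrays are over the harmonic grid; index 0 (DC) carries the Poiseuille
    resistance of the whole segment instead.
    """

    def __init__(self, seg, omega: np.ndarray, wall_damping: float, viscosity: float):
        a = wall_damping
        area = seg.lumen_area
        inertance = BLOOD_DENSITY / area
        r_visc = 8.0 * np.pi * viscosity / (area * area)
        w = omega[1:]  # nonzero harmonics
        z = r_visc + 1j * w * inertance
        y = 1j * w * seg.area_compliance * (1.0 - 1j * a) ** 2
        self.gamma = np.sqrt(z * y)  # principal branch: Re >= 0
        self.gamma = np.where(self.gamma.real < 0, -self.gamma, self.gamma)
        self.zc = np.sqrt(z / y)
        self.zc = np.where(self.zc.real < 0, -self.zc, self.zc)
        self.dc_resistance = r_visc * seg.length
        self.length = seg.length


def _line_zin(lp: _LineParams, z_load_ac: np.ndarray, z_load_dc: float):
    """(AC input impedance over nonzero harmonics, DC input resistance)."""
    gl = lp.gamma * lp.length
    ch, sh = np.cosh(gl), np.sinh(gl)
    zin_ac = lp.zc * (z_load_ac * ch + lp.zc * sh) / (lp.zc * ch + z_load_ac * sh)
    return zin_ac, lp.dc_resistance + z_load_dc


def input_impedance(tree: ArterialTreeModel, omega: np.ndarray,
                    segment: str | None = None,
                    wall_damping: float = DEFAULT_WALL_DAMPING,
                    viscosity: float = DEFAULT_BLOOD_VISCOSITY) -> np.ndarray:
    """Input impedance [Pa s/m^3] seen at the inlet of `segment` (default: root).

    `omega` is an array of angular frequencies; a zero entry is evaluated as
    the DC resistance of the network.
    """
    omega = np.asarray(omega, dtype=float)
    name = segment or tree.root.name
    nonzero = omega != 0.0
    om = np.concatenate([[0.0], omega[nonzero]])
    zin_ac, zin_dc = _zin_recursive(tree, name, om, wall_damping, viscosity)
    out = np.empty(omega.shape, dtype=complex)
    out[~nonzero] = zin_dc
    out[nonzero] = zin_ac
    return out


def _zin_recursive(tree, name, omega, a, mu):
    seg = tree.segments[name]
    lp = _LineParams(seg, omega, a, mu)
    adm_ac = np.zeros(omega.size - 1, dtype=complex)
    adm_dc = 0.0
    term = tree.terminal(name)
    if term is not None:
        adm_ac += 1.0 / term.impedance(omega[1:])
        adm_dc += 1.0 / term.resistance
    for child in tree.children(name):
        z_ac, z_dc = _zin_recursive(tree, child, omega, a, mu)
        adm_ac += 1.0 / z_ac
        adm_dc += 1.0 / z_dc
    return _line_zin(lp, 1.0 / adm_ac, 1.0 / adm_dc)


def solve_hemodynamics(tree: ArterialTreeModel, inflow: CardiacInflow,
                       sampling_rate: float = DEFAULT_SAMPLING_RATE,
                       n_harmonics: int = DEFAULT_N_HARMONICS,
                       subject_id: str | None = None,
                       wall_damping: float = DEFAULT_WALL_DAMPING,
                       viscosity: float = DEFAULT_BLOOD_VISCOSITY) -> dict[str, Waveform]:
    """Periodic steady-state pressure at all named sites + flow at the root.

    Returns a dict keyed by 'pressure:<site>' and 'flow:aortic_root', in
    clinical units (mmHg, mL/s).
    """
    if n_harmonics < 20:
        raise ValueError("at least 20 harmonics must be retained")
    period = inflow.period
    n_samples = int(round(sampling_rate * period))
    t = np.arange(n_samples) / sampling_rate
    q_t = inflow.sample(t)  # m^3/s
    q_hat = np.fft.rfft(q_t)
    k = min(n_harmonics, n_samples // 2)
    omega = 2.0 * np.pi * np.arange(k + 1) / period
    q_harm = q_hat[: k + 1]

    lps: dict[str, _LineParams] = {}
    zin_ac: dict[str, np.ndarray] = {}
    zin_dc: dict[str, float] = {}

    def compute_zin(name: str):
        if name in zin_ac:
            return
        seg = tree.segments[name]
        lps[name] = _LineParams(seg, omega, wall_damping, viscosity)
        adm_ac = np.zeros(k, dtype=complex)
        adm_dc = 0.0
        term = tree.terminal(name)
        if term is not None:
            adm_ac += 1.0 / term.impedance(omega[1:])
            adm_dc += 1.0 / term.resistance
        for child in tree.children(name):
            compute_zin(child)
            adm_ac += 1.0 / zin_ac[child]
            adm_dc += 1.0 / zin_dc[child]
        zin_ac[name], zin_dc[name] = _line_zin(lps[name], 1.0 / adm_ac, 1.0 / adm_dc)

    root = tree.root.name
    compute_zin(root)

    # root pressure spectrum: AC harmonics via Z_in, DC via total resistance
    p_root = np.empty(k + 1, dtype=complex)
    p_root[0] = q_harm[0] * zin_dc[root]
    p_root[1:] = q_harm[1:] * zin_ac[root]

    # propagate (P, Q) at each segment inlet down the tree
    inlet_p: dict[str, np.ndarray] = {root: p_root}
    inlet_q: dict[str, np.ndarray] = {root: q_harm.copy()}
    order = [root]
    i = 0
    while i < len(order):
        name = order[i]
        i += 1
        lp = lps[name]
        p0, q0 = inlet_p[name], inlet_q[name]
        gl = lp.gamma * lp.length
        pf = 0.5 * (p0[1:] + lp.zc * q0[1:])
        pb = 0.5 * (p0[1:] - lp.zc * q0[1:])
        p_end = np.empty(k + 1, dtype=complex)
        p_end[0] = p0[0] - q0[0].real * lp.dc_resistance
        p_end[1:] = pf * np.exp(-gl) + pb * np.exp(gl)
        for child in tree.children(name):
            q_child = np.empty(k + 1, dtype=complex)
            q_child[0] = p_end[0] / zin_dc[child]
            q_child[1:] = p_end[1:] / zin_ac[child]
            inlet_p[child] = p_end
            inlet_q[child] = q_child
            order.append(child)

    def pressure_at(seg_name: str, frac: float) -> np.ndarray:
        lp = lps[seg_name]
        p0, q0 = inlet_p[seg_name], inlet_q[seg_name]
        gx = lp.gamma * frac * lp.length
        pf = 0.5 * (p0[1:] + lp.zc * q0[1:])
        pb = 0.5 * (p0[1:] - lp.zc * q0[1:])
        p = np.empty(k + 1, dtype=complex)
        p[0] = p0[0] - q0[0].real * lp.dc_resistance * frac
        p[1:] = pf * np.exp(-gx) + pb * np.exp(gx)
        return p

    def to_time(harmonics: np.ndarray) -> np.ndarray:
        spectrum = np.zeros(n_samples // 2 + 1, dtype=complex)
        spectrum[: k + 1] = harmonics
        return np.fft.irfft(spectrum, n=n_samples)

    waveforms: dict[str, Waveform] = {}
    who = f" (subject {subject_id})" if subject_id else ""
    for site, (seg_name, frac) in tree.sites.items():
        p = pa_to_mmhg(to_time(pressure_at(seg_name, frac)))
        if np.any(p <= 0):
            raise HemodynamicsError(
                f"non-positive pressure at site {site}{who}; "
                f"parameter set is outside the solvable regime"
            )
        waveforms[f"pressure:{site}"] = Waveform(site, "pressure", p, sampling_rate, "mmHg")

    q_band = m3s_to_mls(to_time(q_harm))
    waveforms["flow:aortic_root"] = Waveform("aortic_root", "flow", q_band,
                                             sampling_rate, "mL/s")
    return waveforms
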