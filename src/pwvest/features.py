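"""Waveform feature extraction and the measurement-noise model.

Implements the intersecting-tangents ("foot-to-foot") pulse-arrival
algorithm, transit-time based pulse wave velocity, brachial cuff-pressure
features (SBP/DBP/MAP), dicrotic-notch and end-of-ejection detection, and
the multiplicative uniform measurement-noise model used to corrupt the
regression features.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .solver import Waveform
from .tree import ArterialTreeModel, travel_length

FEATURE_COLUMNS = ("brSBP", "brDBP", "MAP", "HR", "cfPWV", "crPWV")
TARGET_COLUMNS = ("zao", "ct")


@dataclass
class FeatureVector:
    """Regression inputs for one subject plus the ground-truth targets."""

    brSBP: float
    brDBP: float
    MAP: float
    HR: float
    cfPWV: float
    crPWV: float
    zao_target: float
    ct_target: float
    noisy: bool = False

    def __post_init__(self):
        if self.brSBP <= self.brDBP:
            raise ValueError("brachial SBP must exceed DBP")
        for name in ("brSBP", "brDBP", "MAP", "HR", "cfPWV", "crPWV",
                     "zao_target", "ct_target"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class NoiseSpec:
    """Multiplicative uniform noise: each variable scaled by (1+e),
    e ~ U[-max_level, +max_level]."""

    max_level: float = 0.15
    rng_seed: int = 0
    targets_noised: bool = True

    def __post_init__(self):
        if not (0.0 <= self.max_level < 1.0):
            raise ValueError("max_level must be in [0, 1)")


def _smoothed_derivative(samples: np.ndarray, dt: float) -> np.ndarray:
    """Central-difference derivative smoothed with a 5-point moving average."""
    d = np.gradient(samples, dt)
    kernel = np.ones(5) / 5.0
    # circular smoothing: the waveform is one period of a periodic signal
    return np.convolve(np.concatenate([d[-2:], d, d[:2]]), kernel, mode="valid")


def detect_foot_tangent(wave: Waveform) -> float:
    """Wave foot by the intersecting-tangents method [s].

    The foot is the abscissa where the tangent through the point of maximum
    systolic upstroke slope meets the horizontal line through the waveform
    minimum. The max-slope search is confined to the systolic upstroke — the
    stretch from the (pre-upstroke) waveform minimum to the systolic peak,
    unwrapped across the periodic beat boundary — and the slope maximum is
    refined by quadratic interpolation. The result is reported modulo the
    period (feet are phases of a periodic signal).
    """
    p = wave.samples
    n = p.size
    dt = 1.0 / wave.sampling_rate
    dp = _smoothed_derivative(p, dt)
    i_min = int(np.argmin(p))
    i_peak = int(np.argmax(p))
    # upstroke window from min to peak, unwrapped over the beat boundary
    span = (i_peak - i_min) % n
    if span == 0:
        raise ValueError("flat waveform: no systolic upstroke")
    window = (i_min + np.arange(1, span)) % n
    j = int(np.argmax(dp[window]))
    i_max = int(window[j])
    slope = dp[i_max]
    if slope <= 0:
        raise ValueError("no systolic upstroke: maximum slope is non-positive")
    # quadratic refinement of the slope maximum (sub-sample)
    im, ip = (i_max - 1) % n, (i_max + 1) % n
    d0, d1, d2 = dp[im], dp[i_max], dp[ip]
    denom = d0 - 2.0 * d1 + d2
    delta = 0.5 * (d0 - d2) / denom if denom < 0 else 0.0
    delta = float(np.clip(delta, -0.5, 0.5))
    t_max = (i_max + delta) * dt
    p_at = p[i_max] + delta * (p[ip] - p[im]) / 2.0
    slope_at = d1 + 0.5 * delta * (d2 - d0)
    p_min = float(np.min(p))
    foot = t_max - (p_at - p_min) / slope_at
    return foot % wave.period


def compute_pwv(wave_proximal: Waveform, wave_distal: Waveform,
                travel_length_m: float) -> float:
    """Foot-to-foot pulse wave velocity [m/s].

    Transit time is the distal-minus-proximal foot delay, unwrapped across
    the periodic beat boundary (feet are phases of a periodic signal).
    """
    t_prox = detect_foot_tangent(wave_proximal)
    t_dist = detect_foot_tangent(wave_distal)
    transit = t_dist - t_prox
    period = wave_proximal.period
    if transit <= 0:
        transit += period
    if transit <= 0 or transit >= period:
        raise ValueError("non-positive transit time after unwrapping")
    if abs(t_dist - t_prox) < 0.25 / wave_proximal.sampling_rate:
        raise ValueError("zero transit time: identical wave feet")
    return travel_length_m / transit


def extract_bp_features(waves: dict[str, Waveform]) -> tuple[float, float, float, float]:
    """(brSBP, brDBP, MAP, HR) from the left-brachial pressure waveform.

    SBP/DBP are the waveform extremes, MAP its time average; HR comes from
    the known simulation period (single-beat waveforms).
    """
    key = "pressure:brachial_L"
    if key not in waves:
        raise KeyError("brachial pressure waveform missing")
    w = waves[key]
    sbp = float(np.max(w.samples))
    dbp = float(np.min(w.samples))
    mean = float(np.mean(w.samples))
    hr = 60.0 / w.period
    return sbp, dbp, mean, hr


def aortic_bp_features(waves: dict[str, Waveform]) -> tuple[float, float, float]:
    """(aoSBP, aoDBP, aoPP) from the aortic-root pressure waveform."""
    key = "pressure:aortic_root"
    if key not in waves:
        raise KeyError("aortic pressure waveform missing")
    w = waves[key]
    sbp = float(np.max(w.samples))
    dbp = float(np.min(w.samples))
    return sbp, dbp, sbp - dbp


def subject_pwvs(tree: ArterialTreeModel, waves: dict[str, Waveform]) -> tuple[float, float]:
    """(cfPWV, crPWV) by the tangent method over the tree transmission paths."""
    cf_len = travel_length(tree, "carotid_L", "femoral_L")
    cr_len = travel_length(tree, "carotid_L", "radial_L")
    cf = compute_pwv(waves["pressure:carotid_L"], waves["pressure:femoral_L"], cf_len)
    cr = compute_pwv(waves["pressure:carotid_L"], waves["pressure:radial_L"], cr_len)
    return cf, cr


def apply_noise(features: FeatureVector, spec: NoiseSpec) -> FeatureVector:
    """Corrupt a feature vector with multiplicative uniform noise.

    Every input variable (and, when `targets_noised`, both targets) is
    independently multiplied by (1 + e) with e ~ U[-max_level, +max_level].
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(spec.rng_seed)
    names = list(FEATURE_COLUMNS) + (["zao_target", "ct_target"]
                                     if spec.targets_noised else [])
    factors = 1.0 + rng.uniform(-spec.max_level, spec.max_level, size=len(names))
    updates = {n: getattr(features, n) * f for n, f in zip(names, factors)}
    return replace(features, **updates, noisy=spec.max_level > 0)


def apply_noise_table(table, spec: NoiseSpec, feature_columns=FEATURE_COLUMNS,
                      target_columns=("Zao_true", "CT_true")):
    """Vectorized noise application on a cohort feature DataFrame.

    Returns a copy with every feature column (and target columns when
    requested) multiplied element-wise by independent (1+e) factors.
    """
    rng = np.random.default_rng(spec.rng_seed)
    out = table.copy()
    cols = list(feature_columns) + (list(target_columns) if spec.targets_noised else [])
    for col in cols:
        e = rng.uniform(-spec.max_level, spec.max_level, size=len(out))
        out[col] = out[col].to_numpy() * (1.0 + e)
    return out


def detect_dicrotic_notch(wave: Waveform) -> tuple[float, bool]:
    """Dicrotic notch time [s] on a central pressure waveform.

    First local minimum after the systolic peak within [0.2, 0.6] of the
    period. Returns (time, found); when no local minimum exists the caller
    should fall back to the flow zero-crossing.
    """
    p = wave.samples
    n = p.size
    dt = 1.0 / wave.sampling_rate
    i_peak = int(np.argmax(p))
    lo = max(i_peak + 1, int(0.2 * n))
    hi = int(0.6 * n)
    for i in range(lo + 1, hi):
        if p[i] < p[i - 1] and p[i] <= p[i + 1]:
            return i * dt, True
    return float("nan"), False


def flow_systole_end(flow: Waveform) -> float:
    """End of ejection: first downward zero crossing after peak flow [s]."""
    q = flow.samples
    dt = 1.0 / flow.sampling_rate
    i_peak = int(np.argmax(q))
    for i in range(i_peak + 1, q.size):
        if q[i] <= 0 < q[i - 1]:
            # linear interpolation to the crossing
            frac = q[i - 1] / (q[i - 1] - q[i])
            return (i - 1 + frac) * dt
    raise ValueError("no downward zero crossing after peak flow")
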