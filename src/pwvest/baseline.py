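"""Baseline (normotensive) arterial-tree parameterization and class modifiers.

The default network is a 13-segment reduction of the systemic arterial tree.
Geometry is anatomically plausible (lengths/areas of the main conduits);
segment wave speeds encode the elastic state and imply area compliances via
C_A = A / (rho c^2). Terminal resistances split the total peripheral
resistance by regional flow fractions; terminal compliances split a lumped
peripheral compliance pool the same way.

Hypertensive subjects apply a proximal-to-distal stiffening gradient on the
aorta (compliance reduced most at the root), a milder uniform stiffening
elsewhere, and a raised total peripheral resistance.

The numeric values below were calibrated once so that the accepted virtual
cohort reproduces the target population summaries (brachial/aortic pressures,
PWVs, Z_ao, C_T, TPR); they are plain data and fully user-configurable.
"""

from __future__ import annotations

import copy

from .tree import ArterialSegment, ArterialTreeModel, TerminalWindkessel
from .units import BLOOD_DENSITY, cclinical_to_si, zclinical_to_si

# name, parent, length [m], lumen area [m^2], wave speed [m/s]
# Wave speeds are effective values chosen so that the *foot-to-foot* regional
# PWVs (transit = difference of arrival times at the two sites, length = full
# tree-path sum) reproduce normotensive carotid-femoral / carotid-radial PWV.
BASELINE_SEGMENTS = [
    ("ascending_aorta", None, 0.060, 6.5e-4, 3.85),
    ("brachiocephalic_R", "ascending_aorta", 0.100, 1.0e-4, 9.0),
    ("aortic_arch_a", "ascending_aorta", 0.030, 4.4e-4, 4.20),
    ("carotid_L", "aortic_arch_a", 0.150, 0.42e-4, 7.0),
    ("aortic_arch_b", "aortic_arch_a", 0.040, 2.6e-4, 3.17),
    ("subclavian_L", "aortic_arch_b", 0.050, 0.70e-4, 4.73),
    ("brachial_L", "subclavian_L", 0.250, 0.40e-4, 5.16),
    ("radial_L", "brachial_L", 0.250, 0.20e-4, 5.59),
    ("thoracic_aorta", "aortic_arch_b", 0.160, 1.6e-4, 3.17),
    ("abdominal_aorta", "thoracic_aorta", 0.150, 1.13e-4, 3.57),
    ("visceral", "abdominal_aorta", 0.080, 1.7e-4, 8.0),
    ("iliac_L", "abdominal_aorta", 0.090, 0.63e-4, 4.12),
    ("femoral_L", "iliac_L", 0.250, 0.33e-4, 4.60),
]

# terminal beds: segment -> fraction of cardiac output
TERMINAL_FLOW_FRACTIONS = {
    "brachiocephalic_R": 0.15,
    "carotid_L": 0.10,
    "radial_L": 0.07,
    "visceral": 0.48,
    "femoral_L": 0.20,
}

SITES = {
    "aortic_root": ("ascending_aorta", 0.0),
    "carotid_L": ("carotid_L", 1.0),
    "brachial_L": ("brachial_L", 1.0),
    "radial_L": ("radial_L", 1.0),
    "femoral_L": ("femoral_L", 0.2),
}

BASELINE = {
    "tpr": 0.90,                      # mmHg s/mL, normotensive baseline
    "terminal_compliance_total": 0.15,  # mL/mmHg
    "heart_rate": 73.26,               # bpm (population mean)
    "stroke_volume": 81.18,            # mL (population mean)
}

# hypertensive class modifiers: compliance multipliers (<1 = stiffer)
HYPERTENSIVE = {
    "aortic_stiffening": {
        "ascending_aorta": 0.50,
        "aortic_arch_a": 0.53,
        "aortic_arch_b": 0.56,
        "thoracic_aorta": 0.62,
        "abdominal_aorta": 0.68,
    },
    "peripheral_stiffening": 0.70,   # all other segments + terminal compliances
    "tpr_factor": 1.0,
}


def default_config() -> dict:
    """Full generator configuration as a plain (YAML-serializable) dict."""
    return copy.deepcopy({
        "segments": [list(s) for s in BASELINE_SEGMENTS],
        "terminal_flow_fractions": dict(TERMINAL_FLOW_FRACTIONS),
        "sites": {k: list(v) for k, v in SITES.items()},
        "baseline": dict(BASELINE),
        "hypertensive": {
            "aortic_stiffening": dict(HYPERTENSIVE["aortic_stiffening"]),
            "peripheral_stiffening": HYPERTENSIVE["peripheral_stiffening"],
            "tpr_factor": HYPERTENSIVE["tpr_factor"],
        },
        "sampling_cv": {
            "geometry": 0.02,      # global scale: lengths x g, areas x g^2
            "compliance": 0.25,    # global scale on all compliances
            "resistance": 0.14,    # global scale on terminal resistances
            "segment_compliance_jitter": 0.02,  # independent per segment
            "segment_length_jitter": 0.03,
            "hypertensive_severity": 0.25,  # jitter on stiffening strength
        },
        "heart_rate_sd": 14.9,
        "stroke_volume_sd": 8.03,
        "heart_rate_bounds": [40.0, 120.0],
    })


def build_tree(config: dict | None = None,
               segment_compliance_scale: dict[str, float] | None = None,
               geometry_scale: float = 1.0,
               compliance_scale: float = 1.0,
               resistance_scale: float = 1.0,
               segment_length_scale: dict[str, float] | None = None) -> ArterialTreeModel:
    """Instantiate an ArterialTreeModel from a configuration dict.

    The optional scale arguments implement subject-level variation:
    `geometry_scale` g multiplies lengths by g and areas by g^2;
    `compliance_scale` multiplies every area and terminal compliance;
    per-segment dicts apply additional multipliers (hypertensive stiffening,
    sampling jitter).
    """
    cfg = config or default_config()
    seg_cscale = segment_compliance_scale or {}
    seg_lscale = segment_length_scale or {}
    g = geometry_scale

    segments: dict[str, ArterialSegment] = {}
    for name, parent, length, area, speed in cfg["segments"]:
        area_s = area * g * g
        # baseline C_A from the configured wave speed, then scaled
        c_a = area_s / (BLOOD_DENSITY * speed * speed)
        c_a *= compliance_scale * seg_cscale.get(name, 1.0)
        segments[name] = ArterialSegment(
            name=name,
            length=length * g * seg_lscale.get(name, 1.0),
            lumen_area=area_s,
            area_compliance=c_a,
            parent=parent,
        )

    tpr_si = zclinical_to_si(cfg["baseline"]["tpr"]) * resistance_scale
    ct_term_si = cclinical_to_si(cfg["baseline"]["terminal_compliance_total"])
    ct_term_si *= compliance_scale
    terminals = []
    for seg_name, frac in cfg["terminal_flow_fractions"].items():
        terminals.append(TerminalWindkessel(
            attached_segment=seg_name,
            resistance=tpr_si / frac,
            compliance=ct_term_si * frac * seg_cscale.get(f"terminal:{seg_name}", 1.0),
        ))

    sites = {k: (v[0], float(v[1])) for k, v in cfg["sites"].items()}
    return ArterialTreeModel(segments=segments, terminals=terminals, sites=sites)
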