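import math

import numpy as np
import pytest

from pwvest import (ArterialSegment, ArterialTreeModel, CardiacInflow,
                    TerminalWindkessel, compute_ct, compute_zao, travel_length)
from pwvest.baseline import build_tree, default_config
from pwvest.cohort import sample_subject_parameters
from pwvest.tree import default_ejection_fraction
from pwvest.units import BLOOD_DENSITY, cclinical_to_si


def test_segment_wave_speed_self_consistency():
    seg = ArterialSegment("s", 0.1, 4e-4, 2e-8)
    assert seg.wave_speed ** 2 * BLOOD_DENSITY * seg.area_compliance == pytest.approx(
        seg.lumen_area, rel=1e-9)


@pytest.mark.parametrize("field,value", [("length", -0.1), ("lumen_area", 0.0),
                                         ("area_compliance", -1e-9)])
def test_segment_rejects_nonphysical(field, value):
    kwargs = {"name": "s", "length": 0.1, "lumen_area": 4e-4,
              "area_compliance": 2e-8, field: value}
    with pytest.raises(ValueError):
        ArterialSegment(**kwargs)


def test_zao_square_root_scaling():
    """Quadrupling A*C_A exactly halves the water-hammer impedance."""
    t1 = build_tree()
    cfg = default_config()
    for row in cfg["segments"]:
        row[3] *= 2.0  # area x2 keeps speed-derived C_A: A*C_A scales x4
    t2 = build_tree(cfg)
    assert compute_zao(t2) == pytest.approx(compute_zao(t1) / 2.0, rel=1e-12)


def test_zao_hand_value():
    """rho=1050, A=5e-4 m^2, C_A=1.2e-8 m^2/Pa -> ~0.099 mmHg s/mL."""
    seg = ArterialSegment("root", 0.06, 5.0e-4, 1.2e-8)
    tree = ArterialTreeModel(
        segments={"root": seg},
        terminals=[TerminalWindkessel("root", 1e8, 0.0)],
        sites={n: ("root", 0.0) for n in
               ("aortic_root", "brachial_L", "carotid_L", "radial_L", "femoral_L")})
    expected = math.sqrt(1050.0 / (5.0e-4 * 1.2e-8)) * 1e-6 / 133.322
    assert expected == pytest.approx(0.0992, rel=1e-3)
    assert compute_zao(tree) == pytest.approx(expected, rel=1e-12)


def test_ct_summation_and_empty_terminals():
    """Segments {0.30, 0.50} + terminal 0.34 mL/mmHg -> 1.14 mL/mmHg."""
    def seg_with_vc(name, parent, vc_ml_mmhg):
        c_si = cclinical_to_si(vc_ml_mmhg)
        return ArterialSegment(name, 0.1, 4e-4, c_si / 0.1, parent=parent)

    sites = {n: ("a", 0.0) for n in
             ("aortic_root", "brachial_L", "carotid_L", "radial_L", "femoral_L")}
    tree = ArterialTreeModel(
        segments={"a": seg_with_vc("a", None, 0.30),
                  "b": seg_with_vc("b", "a", 0.50)},
        terminals=[TerminalWindkessel("b", 1e8, cclinical_to_si(0.34))],
        sites=sites)
    assert compute_ct(tree) == pytest.approx(1.14, rel=1e-12)

    tree0 = ArterialTreeModel(
        segments={"a": seg_with_vc("a", None, 0.30),
                  "b": seg_with_vc("b", "a", 0.50)},
        terminals=[TerminalWindkessel("b", 1e8, 0.0)],
        sites=sites)
    assert compute_ct(tree0) == pytest.approx(0.80, rel=1e-12)


def test_ct_additivity_over_partition():
    """C_T equals the sum of per-segment volume compliances plus terminals."""
    tree = build_tree()
    parts = sum(s.volume_compliance for s in tree.segments.values())
    parts += sum(t.compliance for t in tree.terminals)
    from pwvest.units import csi_to_clinical
    assert compute_ct(tree) == pytest.approx(csi_to_clinical(parts), rel=1e-14)


def test_tree_validation_errors():
    seg = ArterialSegment("a", 0.1, 4e-4, 2e-8)
    sites = {n: ("a", 0.0) for n in
             ("aortic_root", "brachial_L", "carotid_L", "radial_L", "femoral_L")}
    with pytest.raises(ValueError, match="terminal"):
        ArterialTreeModel(segments={"a": seg}, terminals=[], sites=sites)
    b = ArterialSegment("b", 0.1, 4e-4, 2e-8, parent="zzz")
    with pytest.raises(ValueError, match="unknown parent"):
        ArterialTreeModel(segments={"a": seg, "b": b},
                          terminals=[TerminalWindkessel("a", 1e8, 0)], sites=sites)
    with pytest.raises(ValueError, match="unknown segment"):
        ArterialTreeModel(segments={"a": seg},
                          terminals=[TerminalWindkessel("a", 1e8, 0)],
                          sites={**sites, "carotid_L": ("nope", 0.5)})


def test_travel_length_same_segment_and_paths():
    tree = build_tree()
    tree.sites["brachial_L"] = ("brachial_L", 0.2)
    tree.sites["radial_L_alt"] = ("brachial_L", 0.8)
    tree.sites["radial_L"] = ("brachial_L", 0.8)
    L = tree.segments["brachial_L"].length
    assert travel_length(tree, "brachial_L", "radial_L") == pytest.approx(0.6 * L)

    tree = build_tree()
    # carotid -> femoral crosses the arch_a junction: sum of listed segments
    expected = (tree.segments["carotid_L"].length
                + tree.segments["aortic_arch_b"].length
                + tree.segments["thoracic_aorta"].length
                + tree.segments["abdominal_aorta"].length
                + tree.segments["iliac_L"].length
                + 0.2 * tree.segments["femoral_L"].length)
    assert travel_length(tree, "carotid_L", "femoral_L") == pytest.approx(expected)
    with pytest.raises(KeyError):
        travel_length(tree, "carotid_L", "elbow")


def test_travel_length_ancestor_case():
    tree = build_tree()
    # aortic_root (ascending, 0.0) is an ancestor-line site of femoral_L
    d = travel_length(tree, "aortic_root", "femoral_L")
    expected = (tree.segments["ascending_aorta"].length
                + tree.segments["aortic_arch_a"].length
                + tree.segments["aortic_arch_b"].length
                + tree.segments["thoracic_aorta"].length
                + tree.segments["abdominal_aorta"].length
                + tree.segments["iliac_L"].length
                + 0.2 * tree.segments["femoral_L"].length)
    assert d == pytest.approx(expected)


@pytest.mark.parametrize("shape", ["asymmetric", "half-sine", "triangular"])
def test_inflow_integral_equals_stroke_volume(shape):
    inflow = CardiacInflow(72.0, 80.0, default_ejection_fraction(72.0),
                           waveform_shape=shape)
    t = np.arange(0, inflow.period, 1e-4)
    volume_ml = np.trapezoid(inflow.sample(t), t) * 1e6
    assert volume_ml == pytest.approx(80.0, rel=1e-3)


def test_sampling_deterministic_under_seed():
    t1, i1, _ = sample_subject_parameters(42, "hypertensive")
    t2, i2, _ = sample_subject_parameters(42, "hypertensive")
    assert i1 == i2
    for name in t1.segments:
        assert t1.segments[name].area_compliance == t2.segments[name].area_compliance
        assert t1.segments[name].length == t2.segments[name].length


def test_sampling_degenerate_zero_cv_returns_baseline():
    cfg = default_config()
    for k in cfg["sampling_cv"]:
        cfg["sampling_cv"][k] = 1e-12
    cfg["heart_rate_sd"] = 1e-12
    cfg["stroke_volume_sd"] = 1e-12
    tree, inflow, _ = sample_subject_parameters(0, "normotensive", cfg)
    ref = build_tree(cfg)
    for name in ref.segments:
        assert tree.segments[name].lumen_area == pytest.approx(
            ref.segments[name].lumen_area, rel=1e-9)
        assert tree.segments[name].area_compliance == pytest.approx(
            ref.segments[name].area_compliance, rel=1e-6)
    assert inflow.heart_rate == pytest.approx(cfg["baseline"]["heart_rate"], rel=1e-9)
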