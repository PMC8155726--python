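"""Virtual-cohort generation.

Subjects are drawn by Gaussian perturbation of the baseline tree (geometry,
compliances, terminal resistances, heart rate, stroke volume), solved to
periodic steady state, summarized (brachial/aortic pressures, tangent-method
PWVs, analytic Z_ao and C_T), and screened by a physiological-validity
filter: a subject is accepted only if all seven checked blood-pressure
quantities lie within mean +/- 2.807 SD (the 99.5% band) of its population
class's reference ranges. Generation repeats until the requested number of
accepted subjects is reached; the whole process is a pure function of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import baseline
from .features import aortic_bp_features, extract_bp_features, subject_pwvs
from .solver import HemodynamicsError, Waveform, solve_hemodynamics
from .tree import (ArterialTreeModel, CardiacInflow, compute_ct, compute_zao,
                   default_ejection_fraction, travel_length)

FILTER_Z = 2.807  # 99.5% two-sided Gaussian band

CHECKED_QUANTITIES = ("brSBP", "brDBP", "MAP", "brPP", "aoSBP", "aoDBP", "aoPP")

#: Reference blood-pressure ranges per population class, (mean, SD) in mmHg.
#: Normotensive values follow large normative cuff/central-BP surveys;
#: hypertensive values follow clinic hypertensive populations. Calibrated so
#: the accepted mixed cohort reproduces the target population summaries.
DEFAULT_REFERENCE_RANGES = {
    "normotensive": {
        "brSBP": (122.0, 16.0), "brDBP": (76.0, 13.0), "MAP": (92.0, 14.0),
        "brPP": (45.0, 12.0), "aoSBP": (123.0, 17.0), "aoDBP": (79.0, 14.0),
        "aoPP": (42.0, 10.5),
    },
    "hypertensive": {
        "brSBP": (153.0, 20.0), "brDBP": (81.0, 16.0), "MAP": (107.0, 17.0),
        "brPP": (70.0, 15.0), "aoSBP": (151.0, 22.0), "aoDBP": (83.0, 17.0),
        "aoPP": (65.0, 13.0),
    },
}


@dataclass
class ReferenceBPRanges:
    """Per-class reference means and SDs for the validity filter."""

    ranges: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_REFERENCE_RANGES.items()})

    def __post_init__(self):
        for cls, quantities in self.ranges.items():
            for q, (_, sd) in quantities.items():
                if sd <= 0:
                    raise ValueError(f"{cls}/{q}: SD must be > 0")

    def interval(self, cls: str, quantity: str) -> tuple[float, float]:
        mean, sd = self.ranges[cls][quantity]
        return mean - FILTER_Z * sd, mean + FILTER_Z * sd


@dataclass
class SubjectRecord:
    """One accepted virtual subject."""

    subject_id: str
    population_class: str
    tree: ArterialTreeModel
    inflow: CardiacInflow
    waveforms: dict[str, Waveform]
    zao_true: float   # mmHg s/mL
    ct_true: float    # mL/mmHg
    total_peripheral_resistance: float  # mmHg s/mL
    summary: dict

    def __post_init__(self):
        if self.zao_true <= 0 or self.ct_true <= 0:
            raise ValueError("ground-truth Z_ao and C_T must be positive")


def _positive_gauss(rng, mean, sd, lo=None, hi=None, floor=1e-6):
    """Gaussian draw redrawn until physical; returns (value, n_redraws)."""
    redraws = 0
    while True:
        x = rng.normal(mean, sd)
        ok = x > floor
        if lo is not None:
            ok = ok and x >= lo
        if hi is not None:
            ok = ok and x <= hi
        if ok:
            return x, redraws
        redraws += 1
        if redraws > 1000:
            raise RuntimeError("sampling failed: non-physical draws persist")


def sample_subject_parameters(rng_seed, population_class: str,
                              config: dict | None = None):
    """Draw one subject parameterization.

    Returns (tree, inflow, info) where info records the redraw count for
    non-physical draws. `rng_seed` may be an int or a numpy Generator.
    Deterministic for a fixed seed.
    """
    if population_class not in ("normotensive", "hypertensive"):
        raise ValueError(f"unknown population class {population_class!r}")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    cfg = config or baseline.default_config()
    cv = cfg["sampling_cv"]
    redraws = 0

    hr_lo, hr_hi = cfg["heart_rate_bounds"]
    hr, r = _positive_gauss(rng, cfg["baseline"]["heart_rate"],
                            cfg["heart_rate_sd"], lo=hr_lo, hi=hr_hi)
    redraws += r
    sv, r = _positive_gauss(rng, cfg["baseline"]["stroke_volume"],
                            cfg["stroke_volume_sd"], lo=20.0)
    redraws += r
    g, r = _positive_gauss(rng, 1.0, cv["geometry"], lo=0.5)
    redraws += r
    kappa, r = _positive_gauss(rng, 1.0, cv["compliance"], lo=0.3)
    redraws += r
    r_scale, r = _positive_gauss(rng, 1.0, cv["resistance"], lo=0.3)
    redraws += r

    seg_scale: dict[str, float] = {}
    len_scale: dict[str, float] = {}
    for name, *_ in cfg["segments"]:
        j, r = _positive_gauss(rng, 1.0, cv["segment_compliance_jitter"], lo=0.3)
        redraws += r
        seg_scale[name] = j
        j, r = _positive_gauss(rng, 1.0, cv["segment_length_jitter"], lo=0.5)
        redraws += r
        len_scale[name] = j

    if population_class == "hypertensive":
        hyp = cfg["hypertensive"]
        sev, r = _positive_gauss(rng, 1.0, cv["hypertensive_severity"], lo=0.2)
        redraws += r
        for name in seg_scale:
            f0 = hyp["aortic_stiffening"].get(name, hyp["peripheral_stiffening"])
            factor = max(1.0 - sev * (1.0 - f0), 0.1)
            seg_scale[name] *= factor
        f_term = max(1.0 - sev * (1.0 - hyp["peripheral_stiffening"]), 0.1)
        for seg_name in cfg["terminal_flow_fractions"]:
            seg_scale[f"terminal:{seg_name}"] = f_term
        r_scale *= 1.0 + sev * (hyp["tpr_factor"] - 1.0)

    tree = baseline.build_tree(cfg, segment_compliance_scale=seg_scale,
                               geometry_scale=g, compliance_scale=kappa,
                               resistance_scale=r_scale,
                               segment_length_scale=len_scale)
    inflow = CardiacInflow(heart_rate=hr, stroke_volume=sv,
                           ejection_fraction_of_period=default_ejection_fraction(hr))
    return tree, inflow, {"redraws": redraws}


def physiological_validity_filter(summary: dict, ranges: ReferenceBPRanges,
                                  population_class: str) -> tuple[bool, list[str]]:
    """Accept iff all seven BP quantities lie within mean +/- 2.807 SD."""
    reasons = []
    for q in CHECKED_QUANTITIES:
        if q not in summary:
            raise KeyError(f"missing quantity {q} in subject summary")
        lo, hi = ranges.interval(population_class, q)
        if not (lo <= summary[q] <= hi):
            reasons.append(q)
    return (len(reasons) == 0), reasons


def _summarize(subject_id: str, cls: str, tree: ArterialTreeModel,
               inflow: CardiacInflow, waves: dict[str, Waveform]) -> dict:
    brsbp, brdbp, mean_p, hr = extract_bp_features(waves)
    aosbp, aodbp, aopp = aortic_bp_features(waves)
    cf, cr = subject_pwvs(tree, waves)
    ao_map = float(np.mean(waves["pressure:aortic_root"].samples))
    co = inflow.stroke_volume * inflow.heart_rate / 60.0  # mL/s
    tpr = ao_map / co  # mean aortic pressure over cardiac output
    return {
        "subject_id": subject_id,
        "class": cls,
        "brSBP": brsbp, "brDBP": brdbp, "brPP": brsbp - brdbp, "MAP": mean_p,
        "aoSBP": aosbp, "aoDBP": aodbp, "aoPP": aopp,
        "SV": inflow.stroke_volume, "HR": hr,
        "Zao_true": compute_zao(tree), "CT_true": compute_ct(tree),
        "TPR": tpr,
        "cfPWV": cf, "crPWV": cr,
        "cf_path_length": travel_length(tree, "carotid_L", "femoral_L"),
        "cr_path_length": travel_length(tree, "carotid_L", "radial_L"),
    }


def generate_cohort(n_subjects: int, hypertensive_fraction: float = 0.5,
                    rng_seed: int = 0, config: dict | None = None,
                    ranges: ReferenceBPRanges | None = None,
                    sampling_rate: float = 1000.0, n_harmonics: int = 40,
                    keep_waveforms=False,
                    out_dir: str | Path | None = None,
                    return_records: bool = False):
    """Generate a validity-filtered virtual cohort.

    Samples, solves and filters until `n_subjects` are accepted. Returns the
    cohort summary table (one row per subject); when `out_dir` is given the
    table is written as ``cohort.csv`` and, if `keep_waveforms`, per-subject
    waveform CSVs under ``waveforms/``. `keep_waveforms` may also be a list
    of waveform keys (e.g. ``["pressure:aortic_root", "flow:aortic_root"]``)
    to retain only those signals. With `return_records` the function returns
    (table, records) where records are the accepted SubjectRecord objects.
    Deterministic under a fixed seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(rng_seed)
    cfg = config or baseline.default_config()
    ranges = ranges or ReferenceBPRanges()

    rows, records = [], []
    attempts = rejected_filter = rejected_solver = 0
    while len(rows) < n_subjects:
        attempts += 1
        if attempts >= 200 and len(rows) / attempts < 0.01:
            raise RuntimeError(
                f"acceptance rate {len(rows) / attempts:.3%} < 1%: "
                "generator calibration does not match the reference BP ranges")
        cls = "hypertensive" if rng.random() < hypertensive_fraction else "normotensive"
        tree, inflow, _info = sample_subject_parameters(rng, cls, cfg)
        sid = f"s{len(rows):05d}"
        try:
            waves = solve_hemodynamics(tree, inflow, sampling_rate, n_harmonics,
                                       subject_id=sid)
        except HemodynamicsError:
            rejected_solver += 1
            continue
        summary = _summarize(sid, cls, tree, inflow, waves)
        ok, _reasons = physiological_validity_filter(summary, ranges, cls)
        if not ok:
            rejected_filter += 1
            continue
        rows.append(summary)
        if keep_waveforms or return_records or out_dir is not None:
            if isinstance(keep_waveforms, (list, tuple, set)):
                kept = {k: waves[k] for k in keep_waveforms}
            elif keep_waveforms:
                kept = waves
            else:
                kept = {}
            records.append(SubjectRecord(
                subject_id=sid, population_class=cls, tree=tree, inflow=inflow,
                waveforms=kept,
                zao_true=summary["Zao_true"], ct_true=summary["CT_true"],
                total_peripheral_resistance=summary["TPR"], summary=summary))

    table = pd.DataFrame(rows)
    table.attrs["attempts"] = attempts
    table.attrs["rejected_filter"] = rejected_filter
    table.attrs["rejected_solver"] = rejected_solver

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "cohort.csv", index=False)
        if keep_waveforms:
            wdir = out / "waveforms"
            wdir.mkdir(exist_ok=True)
            for rec in records:
                for key, wave in rec.waveforms.items():
                    fname = f"{rec.subject_id}_{key.replace(':', '_')}.csv"
                    np.savetxt(wdir / fname,
                               np.column_stack([wave.time, wave.samples]),
                               delimiter=",", header="time_s,value", comments="")
    if return_records:
        return table, records
    return table
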