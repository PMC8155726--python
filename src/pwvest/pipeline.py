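"""End-to-end study pipeline: generate -> featurize -> train -> evaluate ->
compare-classical, driven by one configuration dict and recorded in a run
manifest (seeds, stage outputs, checksums)."""

from __future__ import annotations

import copy
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, baseline
from .classical import (CentralHemodynamics, apply_signal_noise, ct_decay_time,
                        ct_pulse_pressure_method, zao_peak_flow,
                        zao_time_derivative_peaks)
from .cohort import DEFAULT_REFERENCE_RANGES, ReferenceBPRanges, generate_cohort
from .features import NoiseSpec, apply_noise_table
from .regression import (PWVRegression, SplitSpec, cfpwv_only_baseline,
                         split_dataset, training_size_sensitivity)
from .stats import evaluate


def default_study_config() -> dict:
    """Full study configuration (YAML-serializable)."""
    return {
        "cohort": {
            "n_subjects": 3818,
            "hypertensive_fraction": 0.5,
            "sampling_rate": 1000.0,
            "n_harmonics": 40,
            "tree": baseline.default_config(),
            "reference_ranges": {c: {q: list(v) for q, v in d.items()}
                                 for c, d in DEFAULT_REFERENCE_RANGES.items()},
        },
        "noise": {"max_level": 0.15, "targets_noised": True},
        "split": {"train": 0.60, "val": 0.20, "test": 0.20},
        "models": {
            "families": ["forest", "network"],
            "targets": ["zao", "ct"],
            "configurations": ["M1", "M2", "M3", "M4"],
        },
        "sensitivity": {"fractions": list(np.round(np.linspace(0.99, 0.01, 15), 3)),
                        "family": "forest"},
        "learning_curve": {"n_points": 20, "lo": 0.01, "hi": 0.95},
        "seeds": {"cohort": 1, "noise": 2, "split": 3, "model": 4, "permutation": 5},
    }


def load_config(path) -> dict:
    import yaml
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_study_config()
    _deep_update(cfg, user)
    return cfg


def save_config(cfg: dict, path) -> None:
    import yaml
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def _deep_update(base: dict, upd: dict) -> dict:
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class RunManifest:
    """Records config, seeds, per-stage outputs and checksums of a run."""

    def __init__(self, config: dict, out_dir: Path):
        self.out_dir = Path(out_dir)
        self.data = {
            "software": {"package": "pwvest", "version": __version__},
            "config": copy.deepcopy(config),
            "stages": {},
        }

    def record(self, stage: str, outputs: dict[str, Path], seconds: float):
        self.data["stages"][stage] = {
            "seconds": round(seconds, 2),
            "outputs": {name: {"path": str(p.relative_to(self.out_dir)),
                               "sha256": _sha256(p)}
                        for name, p in outputs.items()},
        }

    def save(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, default=str))
        return path


def classical_comparison(records, noise: NoiseSpec) -> pd.DataFrame:
    """Table of classical-method estimates on a set of subject records.

    Each record must carry the central waveforms (pressure and flow at the
    aortic root). Signals are scaled by one random factor each, as in the
    measurement-noise protocol for whole waveforms.
    """
    rng = np.random.default_rng(noise.rng_seed)
    rows = []
    for rec in records:
        h = CentralHemodynamics.from_waveforms(rec.waveforms)
        if noise.max_level > 0:
            h = apply_signal_noise(h, NoiseSpec(noise.max_level,
                                                rng_seed=int(rng.integers(2**31))))
        row = {"subject_id": rec.subject_id,
               "Zao_true": rec.zao_true, "CT_true": rec.ct_true}
        try:
            row["zao_tdp"] = zao_time_derivative_peaks(h)
            row["zao_pf"] = zao_peak_flow(h)
            row["ct_dtm"] = ct_decay_time(h)
            row["ct_ppm"] = ct_pulse_pressure_method(h)
        except (ValueError, RuntimeError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def classical_report(table: pd.DataFrame) -> pd.DataFrame:
    """Agreement statistics of each classical method against ground truth."""
    methods = [("zao_tdp", "Zao_true", "time-derivative peaks"),
               ("zao_pf", "Zao_true", "peak flow"),
               ("ct_dtm", "CT_true", "decay time"),
               ("ct_ppm", "CT_true", "pulse pressure")]
    rows = []
    for col, truth, label in methods:
        ok = table[col].notna() if col in table else pd.Series(False, index=table.index)
        sub = table[ok]
        if len(sub) < 3:
            continue
        rep = evaluate(sub[col], sub[truth])
        err = 100.0 * (sub[col] - sub[truth]) / sub[truth]
        rows.append({"method": label, "target": truth,
                     "estimate_mean": sub[col].mean(), "estimate_sd": sub[col].std(),
                     "reference_mean": sub[truth].mean(), "reference_sd": sub[truth].std(),
                     "error_min_pct": err.min(), "error_max_pct": err.max(),
                     "n": rep.n, "r": rep.pearson_r, "rmse": rep.rmse,
                     "nrmse_pct": rep.nrmse, "bias": rep.bias,
                     "loa_low": rep.loa_low, "loa_high": rep.loa_high})
    return pd.DataFrame(rows)


def run_full_study(config: dict | None = None, out_dir="study_out",
                   progress: bool = True) -> dict:
    """Run the complete pipeline and write all result tables.

    Produces, under `out_dir`: cohort.csv, features_noisy.csv,
    cohort_summary.csv (population statistics), correlations.csv,
    model_report.csv (all family x target x configuration runs),
    hyperparameters.csv, importances.csv, learning_curve_*.csv,
    sensitivity.csv, cfpwv_only.csv, classical.csv and classical_report.csv,
    plus manifest.json. Returns {"manifest": path, "tables": {...}}.
    """
    cfg = config or default_study_config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(cfg, out)
    seeds = cfg["seeds"]
    tables: dict[str, pd.DataFrame] = {}

    def log(msg):
        if progress:
            print(f"[pwvest] {msg}", flush=True)

    # ---- stage 1: cohort ---------------------------------------------------
    t0 = time.time()
    ccfg = cfg["cohort"]
    cohort, records = generate_cohort(
        ccfg["n_subjects"], ccfg["hypertensive_fraction"], rng_seed=seeds["cohort"],
        config=ccfg["tree"],
        ranges=ReferenceBPRanges({c: {q: tuple(v) for q, v in d.items()}
                                  for c, d in ccfg["reference_ranges"].items()}),
        sampling_rate=ccfg["sampling_rate"], n_harmonics=ccfg["n_harmonics"],
        keep_waveforms=["pressure:aortic_root", "flow:aortic_root"],
        return_records=True)
    cohort_path = out / "cohort.csv"
    cohort.to_csv(cohort_path, index=False)
    summary = cohort.describe().T[["mean", "std"]]
    summary_path = out / "cohort_summary.csv"
    summary.to_csv(summary_path)
    log(f"cohort: {len(cohort)} subjects ({cohort.attrs['attempts']} attempts)")
    manifest.record("generate", {"cohort": cohort_path, "summary": summary_path},
                    time.time() - t0)
    tables["cohort"] = cohort

    # ---- stage 2: features + noise ----------------------------------------
    t0 = time.time()
    noise = NoiseSpec(cfg["noise"]["max_level"], rng_seed=seeds["noise"],
                      targets_noised=cfg["noise"]["targets_noised"])
    noisy = apply_noise_table(cohort, noise)
    feat_path = out / "features_noisy.csv"
    noisy.to_csv(feat_path, index=False)
    corr_rows = []
    for f in ["brSBP", "brDBP", "HR", "cfPWV", "crPWV"]:
        for t in ["Zao_true", "CT_true"]:
            corr_rows.append({"feature": f, "target": t,
                              "r_clean": cohort[f].corr(cohort[t]),
                              "r_noisy": noisy[f].corr(noisy[t])})
    corr = pd.DataFrame(corr_rows)
    corr_path = out / "correlations.csv"
    corr.to_csv(corr_path, index=False)
    manifest.record("featurize", {"features": feat_path, "correlations": corr_path},
                    time.time() - t0)
    tables["correlations"] = corr

    # ---- stage 3: models ---------------------------------------------------
    t0 = time.time()
    split = SplitSpec(cfg["split"]["train"], cfg["split"]["val"],
                      cfg["split"]["test"], rng_seed=seeds["split"])
    model_rows, hp_rows = [], []
    m1_results = {}
    for family in cfg["models"]["families"]:
        for target in cfg["models"]["targets"]:
            for conf in cfg["models"]["configurations"]:
                res = PWVRegression(noisy, target=target, family=family,
                                    configuration=conf, split=split,
                                    rng_seed=seeds["model"]).fit()
                rep = res.report
                model_rows.append({"family": family, "target": target,
                                   "configuration": conf, "slope": rep.slope,
                                   "intercept": rep.intercept, "r": rep.pearson_r,
                                   "p": rep.wald_p, "rmse": rep.rmse,
                                   "nrmse_pct": rep.nrmse, "bias": rep.bias,
                                   "loa_low": rep.loa_low, "loa_high": rep.loa_high})
                if conf == "M1":
                    hp_rows.append({"family": family, "target": target,
                                    **res.chosen_hyperparameters})
                    m1_results[(family, target)] = res
                log(f"{family}/{target}/{conf}: nRMSE {rep.nrmse:.2f}% r {rep.pearson_r:.3f}")
    model_report = pd.DataFrame(model_rows)
    model_path = out / "model_report.csv"
    model_report.to_csv(model_path, index=False)
    hp_path = out / "hyperparameters.csv"
    pd.DataFrame(hp_rows).to_csv(hp_path, index=False)
    manifest.record("train_evaluate", {"models": model_path, "hyperparameters": hp_path},
                    time.time() - t0)
    tables["models"] = model_report

    # permutation importances (forest, M1)
    t0 = time.time()
    imp_rows = []
    for target in cfg["models"]["targets"]:
        res = m1_results.get(("forest", target))
        if res is None:
            continue
        imp = res.permutation_importance(n_repeats=20, rng_seed=seeds["permutation"])
        imp["target"] = target
        imp_rows.append(imp)
    importances = pd.concat(imp_rows, ignore_index=True) if imp_rows else pd.DataFrame()
    imp_path = out / "importances.csv"
    importances.to_csv(imp_path, index=False)
    manifest.record("importances", {"importances": imp_path}, time.time() - t0)
    tables["importances"] = importances

    # learning curves (forest, M1, both targets)
    t0 = time.time()
    lc_paths = {}
    for target in cfg["models"]["targets"]:
        model = PWVRegression(noisy, target=target, family="forest",
                              configuration="M1", split=split, rng_seed=seeds["model"])
        lc = model.learning_curve(**cfg["learning_curve"])
        p = out / f"learning_curve_{target}.csv"
        lc.to_csv(p, index=False)
        lc_paths[target] = p
        tables[f"learning_curve_{target}"] = lc
    manifest.record("learning_curves", lc_paths, time.time() - t0)

    # training-size sensitivity
    t0 = time.time()
    sens_frames = []
    for target in cfg["models"]["targets"]:
        sens = training_size_sensitivity(
            noisy, target=target, family=cfg["sensitivity"]["family"],
            configuration="M1", fractions=cfg["sensitivity"]["fractions"],
            split=split, rng_seed=seeds["model"])
        sens["target"] = target
        sens_frames.append(sens)
    sensitivity = pd.concat(sens_frames, ignore_index=True)
    sens_path = out / "sensitivity.csv"
    sensitivity.to_csv(sens_path, index=False)
    manifest.record("sensitivity", {"sensitivity": sens_path}, time.time() - t0)
    tables["sensitivity"] = sensitivity

    # cfPWV-only baseline for C_T
    t0 = time.time()
    base_res = cfpwv_only_baseline(noisy, target="ct", family="network",
                                   split=split, rng_seed=seeds["model"])
    rep = base_res.report
    baseline_df = pd.DataFrame([{"family": "network", "target": "ct",
                                 "configuration": "cfPWV_only",
                                 "nrmse_pct": rep.nrmse, "r": rep.pearson_r,
                                 "bias": rep.bias, "loa_low": rep.loa_low,
                                 "loa_high": rep.loa_high}])
    base_path = out / "cfpwv_only.csv"
    baseline_df.to_csv(base_path, index=False)
    manifest.record("cfpwv_only", {"cfpwv_only": base_path}, time.time() - t0)
    tables["cfpwv_only"] = baseline_df

    # classical comparators on the test subjects
    t0 = time.time()
    _, _, test = split_dataset(noisy, split)
    test_ids = set(test["subject_id"])
    test_records = [r for r in records if r.subject_id in test_ids]
    classical = classical_comparison(test_records,
                                     NoiseSpec(cfg["noise"]["max_level"],
                                               rng_seed=seeds["noise"] + 1))
    cls_path = out / "classical.csv"
    classical.to_csv(cls_path, index=False)
    cls_report = classical_report(classical)
    clsr_path = out / "classical_report.csv"
    cls_report.to_csv(clsr_path, index=False)
    manifest.record("compare_classical", {"estimates": cls_path, "report": clsr_path},
                    time.time() - t0)
    tables["classical_report"] = cls_report

    manifest_path = manifest.save()
    log(f"manifest: {manifest_path}")
    return {"manifest": manifest_path, "tables": tables, "out_dir": out}
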