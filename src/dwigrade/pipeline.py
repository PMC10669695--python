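"""Pipeline orchestration: simulate → fit → measure → analyze → classify → report.

Every stage consumes and produces plain files inside one run directory, so
any contiguous subset of stages can be re-run; all randomness flows from
the single master seed in the configuration, making re-runs with the same
config byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .classification import (
    CLASSIFIERS,
    assemble_features,
    cross_validate,
    delong_test,
    parameter_roc,
    performance_table,
)
from .fitting import FitConfig, fit_parameter_maps, save_param_maps
from .group_analysis import compare_all_parameters, correlation_matrix
from .signal_models import BScheme
from .synthetic_data import (
    PARAM_ORDER,
    PRINTED_SCALE,
    GroupDistributionSpec,
    PhantomSpec,
    simulate_cohort,
)
from .voi_stats import average_observers, icc_two_way, whole_lesion_mean
from .volume import load_dwi, load_mask

__all__ = ["RunConfig", "OrchestrationError", "run_pipeline",
           "exclusion_report", "STAGES"]

STAGES = ("simulate", "fit", "measure", "analyze", "classify", "report")


class OrchestrationError(RuntimeError):
    """A stage is missing an input artifact from an upstream stage."""


@dataclass
class RunConfig:
    """Master configuration of one reproducible pipeline run."""

    seed: int = 0
    n_low: int = 20
    n_high: int = 12
    snr: float = 50.0
    grid_shape: tuple[int, int, int] = (16, 16, 8)
    lesion_radius: float = 3.0
    observer_perturbation: float = 1.0
    cv_folds: int = 5
    #: "observers" fits only within the dilated union of observer VOIs
    fit_mask: str = "observers"
    parameters: tuple[str, ...] = PARAM_ORDER

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        self.grid_shape = tuple(int(x) for x in self.grid_shape)
        self.parameters = tuple(self.parameters)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def exclusion_report(enrolled: int, exclusions: dict[str, int]) -> dict:
    """Cohort-flow accounting: included = enrolled − sum of exclusions."""
    if any(v < 0 for v in exclusions.values()) or enrolled < 0:
        raise ValueError("counts must be non-negative")
    total_excluded = sum(exclusions.values())
    if total_excluded > enrolled:
        raise ValueError("exclusions exceed the enrolled count")
    flow = [{"step": "enrolled", "excluded": 0, "remaining": enrolled}]
    remaining = enrolled
    for reason, count in exclusions.items():
        remaining -= count
        flow.append({"step": reason, "excluded": count, "remaining": remaining})
    return {"enrolled": enrolled, "included": remaining, "flow": flow}


def _stamp(outdir: Path, config: RunConfig, stage: str) -> None:
    meta = {"stage": stage, "seed": config.seed, "config_hash": config.digest()}
    (outdir / f".{stage}.stamp.json").write_text(json.dumps(meta, indent=2))


def _require_artifact(path: Path, stage: str) -> Path:
    if not path.exists():
        raise OrchestrationError(
            f"stage '{stage}' is missing its input artifact: {path}")
    return path


def _log(lines: list[str], outdir: Path, name: str) -> None:
    (outdir / name).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------- stages


def stage_simulate(config: RunConfig, outdir: Path) -> None:
    spec = PhantomSpec(shape=config.grid_shape,
                       lesion_radius=config.lesion_radius, snr=config.snr)
    cohort = simulate_cohort(
        config.n_low, config.n_high, config.seed,
        dist_spec=GroupDistributionSpec(), phantom_spec=spec,
        observer_perturbation=config.observer_perturbation)
    cohort.save(outdir / "simulate", write_volumes=True)
    _stamp(outdir / "simulate", config, "simulate")


def stage_fit(config: RunConfig, outdir: Path) -> None:
    sim = _require_artifact(outdir / "simulate" / "cohort.csv", "fit").parent
    table = pd.read_csv(sim / "cohort.csv")
    fit_dir = outdir / "fit"
    fit_dir.mkdir(parents=True, exist_ok=True)
    cfg = FitConfig()
    log = []
    for pid in table["patient_id"]:
        pdir = sim / pid
        vol = load_dwi(pdir / "dwi.nii.gz", sim / "btable.csv")
        if config.fit_mask == "observers":
            union = np.zeros(vol.shape, dtype=bool)
            for mask_path in sorted(pdir.glob("voi_obs*.nii.gz")):
                m, _ = load_mask(mask_path)
                union |= m
            mask = ndimage.binary_dilation(union, iterations=1)
        else:
            mask = None
        maps = fit_parameter_maps(vol, mask=mask, cfg=cfg)
        save_param_maps(maps, fit_dir / pid, cfg)
        rep = maps.report()
        log.append(f"{pid}: fitted {rep['n_fitted']}, "
                   f"converged {rep['n_converged']}")
    _log(log, fit_dir, "fit_log.txt")
    _stamp(fit_dir, config, "fit")


def stage_measure(config: RunConfig, outdir: Path) -> None:
    import nibabel as nib

    sim = _require_artifact(outdir / "simulate" / "cohort.csv", "measure").parent
    fit_dir = _require_artifact(outdir / "fit" / "fit_log.txt", "measure").parent
    table = pd.read_csv(sim / "cohort.csv")
    meas_dir = outdir / "measure"
    meas_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for _, prow in table.iterrows():
        pid = prow["patient_id"]
        maps = {}
        for param in config.parameters:
            img = nib.load(str(fit_dir / pid / f"{param}.nii.gz"))
            maps[param] = np.asarray(img.dataobj, dtype=float)
        for obs_idx, mask_path in enumerate(
                sorted((sim / pid).glob("voi_obs*.nii.gz")), 1):
            voi, _ = load_mask(mask_path)
            for param in config.parameters:
                rows.append({"patient_id": pid, "grade": prow["grade"],
                             "parameter": param, "observer": obs_idx,
                             "value": whole_lesion_mean(maps[param], voi)})
    tidy = pd.DataFrame(rows)
    tidy.to_csv(meas_dir / "measurements.csv", index=False)

    # per-patient averaged-observer values on the printed reporting scale
    agg_rows = []
    for pid, sub in tidy.groupby("patient_id", sort=False):
        rec = {"patient_id": pid, "grade": sub["grade"].iloc[0]}
        for param in config.parameters:
            vals = sub.loc[sub["parameter"] == param, "value"].to_numpy()
            rec[param] = average_observers(vals) / PRINTED_SCALE[param]
        agg_rows.append(rec)
    pd.DataFrame(agg_rows).to_csv(meas_dir / "patients.csv", index=False)

    icc_rows = []
    for param in config.parameters:
        wide = tidy[tidy["parameter"] == param].pivot(
            index="patient_id", columns="observer", values="value")
        res = icc_two_way(wide.to_numpy())
        icc_rows.append({"parameter": param, "icc": res.icc,
                         "ci_low": res.ci_low, "ci_high": res.ci_high,
                         "band": res.band})
    pd.DataFrame(icc_rows).to_csv(meas_dir / "icc.csv", index=False)
    _stamp(meas_dir, config, "measure")


def stage_analyze(config: RunConfig, outdir: Path) -> None:
    meas = _require_artifact(outdir / "measure" / "patients.csv", "analyze")
    patients = pd.read_csv(meas)
    ana_dir = outdir / "analyze"
    ana_dir.mkdir(parents=True, exist_ok=True)

    comparisons = compare_all_parameters(patients, config.parameters)
    comparisons.to_csv(ana_dir / "group_comparisons.csv", index=False)
    corr = correlation_matrix(patients, config.parameters)
    corr.r.to_csv(ana_dir / "correlation_r.csv")
    corr.p.to_csv(ana_dir / "correlation_p.csv")
    corr.method.to_csv(ana_dir / "correlation_method.csv")

    lines = ["Group comparisons (low vs high grade)", "=" * 40]
    for _, r in comparisons.iterrows():
        lines.append(
            f"{r['parameter']:>5}: {r['test_used']:<12} p = {r['p_value']:.4g}  "
            f"low {r['mean_low']:.4g} ± {r['sd_low']:.3g}, "
            f"high {r['mean_high']:.4g} ± {r['sd_high']:.3g}")
    _log(lines, ana_dir, "report.txt")
    _stamp(ana_dir, config, "analyze")


def stage_classify(config: RunConfig, outdir: Path) -> None:
    meas = _require_artifact(outdir / "measure" / "patients.csv", "classify")
    patients = pd.read_csv(meas)
    cls_dir = outdir / "classify"
    cls_dir.mkdir(parents=True, exist_ok=True)

    features = assemble_features(patients)
    y = features["label"].to_numpy(int)

    cv_json = {}
    lg_oof = None
    for kind in CLASSIFIERS:
        cv = cross_validate(features, kind, k=config.cv_folds, seed=config.seed)
        if kind == "LG":
            lg_oof = cv.oof_scores
        cv_json[kind] = {
            "fold_aucs": list(cv.fold_aucs), "mean_auc": cv.mean_auc,
            "ci_low": cv.ci_low, "ci_high": cv.ci_high,
            "sensitivity": cv.sens_at_youden,
            "specificity": cv.spec_at_youden,
            "youden_index": cv.youden_index,
        }
    (cls_dir / "cv_results.json").write_text(json.dumps(cv_json, indent=2))

    perf = performance_table(features, patients, config.parameters,
                             k=config.cv_folds, seed=config.seed)
    perf.to_csv(cls_dir / "performance_table.csv", index=False)

    # DeLong: pooled out-of-fold LG scores vs each raw parameter
    delong_rows = []
    for param in config.parameters:
        _, sign = parameter_roc(patients[param].to_numpy(float), y)
        res = delong_test(lg_oof, sign * patients[param].to_numpy(float), y)
        delong_rows.append({"comparison": f"LG_vs_{param}",
                            "auc_lg": res.auc_a, "auc_param": res.auc_b,
                            "z": res.z, "p_value": res.p_value})
    pd.DataFrame(delong_rows).to_csv(cls_dir / "delong.csv", index=False)

    roc_full = parameter_roc(lg_oof, y, direction="auto")[0]
    pd.DataFrame({"threshold": roc_full.thresholds,
                  "sensitivity": roc_full.sensitivity,
                  "specificity": roc_full.specificity}).to_csv(
        cls_dir / "roc_lg_oof.csv", index=False)
    _stamp(cls_dir, config, "classify")


def stage_report(config: RunConfig, outdir: Path) -> None:
    cls_dir = _require_artifact(outdir / "classify" / "cv_results.json", "report")
    icc_path = _require_artifact(outdir / "measure" / "icc.csv", "report")
    rep_dir = outdir / "report"
    rep_dir.mkdir(parents=True, exist_ok=True)

    cv = json.loads(cls_dir.read_text())
    icc = pd.read_csv(icc_path)
    lines = [f"Run {config.digest()} (seed {config.seed})", ""]
    lines.append("Inter-observer agreement (ICC):")
    for _, r in icc.iterrows():
        lines.append(f"  {r['parameter']:>5}: {r['icc']:.3f} "
                     f"[{r['ci_low']:.3f}, {r['ci_high']:.3f}] ({r['band']})")
    lines.append("")
    lines.append("Cross-validated classifiers:")
    for kind, d in cv.items():
        lines.append(f"  {kind:>4}: mean AUC {d['mean_auc']:.3f} "
                     f"[{d['ci_low']:.3f}, {d['ci_high']:.3f}]  "
                     f"sens {d['sensitivity']:.3f} spec {d['specificity']:.3f} "
                     f"Youden {d['youden_index']:.3f}")
    _log(lines, rep_dir, "summary.txt")
    (rep_dir / "config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True))
    _stamp(rep_dir, config, "report")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "fit": stage_fit,
    "measure": stage_measure,
    "analyze": stage_analyze,
    "classify": stage_classify,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, outdir: str | Path,
                 stages: tuple[str, ...] | None = None) -> Path:
    """Execute the requested stages (default: all) into a run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    selected = stages or STAGES
    for stage in selected:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage: {stage!r}")
    for stage in STAGES:
        if stage in selected:
            _STAGE_FUNCS[stage](config, outdir)
    return outdir
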