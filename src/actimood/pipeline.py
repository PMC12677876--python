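"""End-to-end orchestration: simulate -> features -> met -> associate ->
classify, from one configuration mapping, with a reproducibility manifest.

The manifest records the configuration hash, the seed, per-stage output
checksums (CSV/JSON only; image files are excluded because their encoders
are not bit-stable across library versions) and a counts ledger. Two runs
with the same configuration and seed produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .associations import AssociationAnalysis
from .cohort import generate_cohort, read_cohort_csv
from .config import ClassifierConfig, FeatureConfig, GeneratorConfig
from .actigraphy import compute_daily_features
from .errors import StageError, ValidationError
from .met import apply_cohort_filters, compute_met_daily
from .severity import run_experiment

log = logging.getLogger(__name__)

REQUIRED_KEYS = ("cohort", "features", "association", "classifier", "seed")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = __version__
    stages: list = field(default_factory=list)
    counts: dict = field(default_factory=dict)

    def add_stage(self, name: str, outputs: dict) -> None:
        self.stages.append({"stage": name, "outputs": outputs})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _checksums(paths) -> dict:
    return {
        Path(p).name: _sha256(p)
        for p in paths
        if Path(p).suffix in (".csv", ".json")
    }


def load_config(source) -> dict:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(source)
    missing = [k for k in REQUIRED_KEYS if k not in cfg]
    if missing:
        raise ValidationError(f"missing config keys: {', '.join(sorted(missing))}")
    return cfg


def _generator_config(cfg: dict, seed: int) -> GeneratorConfig:
    section = dict(cfg["cohort"] or {})
    if "days_per_patient" in section:
        section["days_per_patient"] = tuple(section["days_per_patient"])
    if "rating_times" in section:
        section["rating_times"] = tuple(section["rating_times"])
    return GeneratorConfig(**section, seed=seed)


def run_all(config, out_dir, seed: int | None = None, resume: bool = False
            ) -> RunManifest:
    """Execute every stage in order; the manifest is written regardless of
    failure, and a stage failure raises :class:`StageError` with the stage
    name. ``resume=True`` skips stages whose outputs already exist."""
    cfg = load_config(config)
    seed = int(cfg["seed"] if seed is None else seed)
    gen_cfg = _generator_config(cfg, seed)
    gen_cfg.validate()  # fail before any stage runs (e.g. 0 patients)
    feat_cfg = FeatureConfig(**(cfg["features"] or {}))
    assoc_cfg = dict(cfg["association"] or {})
    clf_section = dict(cfg["classifier"] or {})
    if "model_menu" in clf_section:
        clf_section["model_menu"] = tuple(clf_section["model_menu"])
    clf_cfg = ClassifierConfig(**clf_section, seed=seed)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    canon = json.dumps(cfg, sort_keys=True, default=str)
    manifest = RunManifest(
        config_hash=hashlib.sha256(canon.encode()).hexdigest(), seed=seed
    )
    stage = "simulate"
    try:
        # -- simulate ------------------------------------------------------
        sim_files = [out / f"{n}.csv" for n in ("epochs", "met", "patients", "sleep")]
        if not (resume and all(p.exists() for p in sim_files)):
            cohort = generate_cohort(gen_cfg)
            cohort.to_csv(out)
        else:
            cohort = read_cohort_csv(out)
        manifest.add_stage(stage, _checksums(sim_files))
        manifest.counts["patients"] = int(len(cohort.patients))
        manifest.counts["patient_days"] = int(len(cohort.epochs) // 1440)

        # -- features ------------------------------------------------------
        stage = "features"
        feat_path = out / "daily_features.csv"
        if resume and feat_path.exists():
            daily_features = pd.read_csv(
                feat_path, dtype={"patient_id": str, "date": str}
            )
        else:
            daily_features = compute_daily_features(cohort.epochs, feat_cfg)
            daily_features.to_csv(feat_path, index=False)
        manifest.add_stage(stage, _checksums([feat_path]))

        # -- met -----------------------------------------------------------
        stage = "met"
        met_path = out / "met_daily.csv"
        met_daily = compute_met_daily(cohort.met)
        met_daily.to_csv(met_path, index=False)
        patients_f, days_f, ledger = apply_cohort_filters(
            cohort.patients, met_daily, daily_features
        )
        ledger.to_json(out / "exclusion_ledger.json")
        patients_f.to_csv(out / "patients_filtered.csv", index=False)
        manifest.add_stage(
            stage, _checksums([met_path, out / "exclusion_ledger.json",
                               out / "patients_filtered.csv"])
        )
        manifest.counts["patients_after_filters"] = int(len(patients_f))
        manifest.counts["days_after_filters"] = int(len(days_f))
        manifest.counts["days_excluded"] = int(len(met_daily) - len(days_f))

        # -- associate -----------------------------------------------------
        stage = "associate"
        res = AssociationAnalysis(
            daily_features, days_f, patients_f,
            min_days=int(assoc_cfg.get("min_days", 50)),
            corrected_alpha=float(assoc_cfg.get("corrected_alpha", 0.004)),
        ).fit()
        res.to_csv(out / "associations.csv")
        res.comparisons.to_csv(out / "group_comparisons.csv", index=False)
        res.plot_heatmaps(out / "heatmaps")
        manifest.add_stage(
            stage,
            _checksums([out / "associations.csv", out / "group_comparisons.csv"]),
        )

        # -- classify ------------------------------------------------------
        stage = "classify"
        report = run_experiment(
            daily_features.merge(
                days_f[["patient_id", "date"]], on=["patient_id", "date"]
            ),
            days_f, patients_f, clf_cfg,
        )
        cv_rows = []
        for target, tr in report["targets"].items():
            for name, agg in tr["models"].items():
                cv_rows.append({"target": target, "model": name, **agg})
            tr["importance"].to_csv(
                out / f"importance_{target}.csv", index=False
            )
        pd.DataFrame(cv_rows).to_csv(out / "cv_metrics.csv", index=False)
        slim = {
            "class_balance": report["class_balance"],
            "targets": {
                t: {"best_model": tr["best_model"], "models": tr["models"]}
                for t, tr in report["targets"].items()
            },
        }
        with open(out / "report.json", "w") as fh:
            json.dump(slim, fh, indent=2)
        manifest.add_stage(
            stage,
            _checksums([out / "cv_metrics.csv", out / "report.json"]
                       + [out / f"importance_{t}.csv"
                          for t in report["targets"]]),
        )
        for t, cb in report["class_balance"].items():
            manifest.counts[f"labels_{t}"] = cb
    except Exception as exc:  # manifest written even on failure
        manifest.to_json(out / "manifest.json")
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, str(exc)) from exc
    manifest.to_json(out / "manifest.json")
    return manifest
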