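"""End-to-end orchestration: simulate → spectra → features → OLO → evaluate.

A :class:`RunConfig` holds every stage's configuration plus one global seed;
each stochastic stage draws its own seed deterministically from the global
seed and the stage name, so a rerun with the same configuration reproduces
every output byte for byte. The :class:`RunManifest` records the
configuration snapshot, software version, and a SHA-256 digest of every
artifact the run writes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarkers import aggregate_patient, select_biomarkers, well_candidates
from .classifier import NetworkConfig, olo_cross_validate
from .evaluation import (
    binary_collapse_metrics,
    confusion_matrix,
    exact_ci,
    per_class_accuracy,
    three_class_accuracy,
)
from .io import write_cohort, write_outcomes
from .synthetic import (
    AcquisitionConfig,
    CohortSpec,
    SyntheticCohort,
    default_phenotypes,
    generate_cohort,
)

log = logging.getLogger("bdiflow")

__all__ = [
    "RunConfig",
    "RunManifest",
    "stage_seed",
    "cohort_candidates",
    "evaluate_predictions",
    "run_pipeline",
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


@dataclass
class RunConfig:
    """Configuration for a full synthetic run."""

    seed: int = 0
    outdir: str = "results/run"
    n_patients_per_grade: tuple[int, int, int] = (6, 6, 6)
    wells_per_patient: int = 16
    arms: tuple[str, ...] = ("cisplatin",)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    k_features: int = 20
    floor_fraction: float = 1e-4
    inhibition_threshold: float = 0.2
    write_cohort_h5: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict[str, Any] = {}
        for key, value in raw.items():
            if key == "acquisition":
                kwargs[key] = AcquisitionConfig(
                    **{
                        k: tuple(v) if isinstance(v, list) else v
                        for k, v in value.items()
                    }
                )
            elif key == "network":
                kwargs[key] = NetworkConfig(
                    **{
                        k: tuple(v) if isinstance(v, list) else v
                        for k, v in value.items()
                    }
                )
            elif isinstance(value, list):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def snapshot(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}


@dataclass
class RunManifest:
    """Record of one pipeline run: config, versions, artifact digests."""

    config: dict
    version: str
    started_utc: str
    stages: dict[str, dict] = field(default_factory=dict)

    def add_stage(self, name: str, outputs: dict[str, Path], status: str = "ok") -> None:
        self.stages[name] = {
            "status": status,
            "outputs": {
                key: {"path": str(p), "sha256": _digest(p)} for key, p in outputs.items()
            },
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def _digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def cohort_candidates(
    cohort: SyntheticCohort,
    floor_fraction: float = 1e-4,
    inhibition_threshold: float = 0.2,
) -> pd.DataFrame:
    """Per-patient raw candidate biomarkers on the administered arm.

    Each patient's replicate wells are reduced to the candidate panel and
    aggregated by the median, using only the arm matching the administered
    regimen (the clinical protocol's arm-matching rule).
    """
    fs = cohort.acquisition.frame_rate_hz
    rows = {}
    for _, rec in cohort.grades.iterrows():
        pid, arm = rec["patient_id"], rec["arm"]
        wells = cohort.series[(pid, arm)]
        per_well = [
            well_candidates(
                wells[w],
                cohort.burst_times_hr,
                cohort.n_baseline_bursts,
                fs,
                floor_fraction=floor_fraction,
                inhibition_threshold=inhibition_threshold,
            )
            for w in range(wells.shape[0])
        ]
        rows[pid] = aggregate_patient(per_well, pid, arm).values
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def evaluate_predictions(predictions: pd.DataFrame, truths: pd.Series) -> dict:
    """All reported clinical statistics from an OLO predictions table."""
    scored = predictions[predictions["graded"]] if "graded" in predictions else predictions
    cm = confusion_matrix(
        dict(zip(scored["patient_id"], scored["predicted"])),
        {p: str(truths[p]) for p in scored["patient_id"]},
    )
    acc, acc_frac = three_class_accuracy(cm)
    per_class = per_class_accuracy(cm)
    binary = binary_collapse_metrics(cm, positive={"0"})
    lo, hi = exact_ci(acc_frac[0], acc_frac[1])
    return {
        "confusion_matrix": cm.counts.tolist(),
        "class_order": list(cm.class_order),
        "three_class_accuracy": {"fraction": acc, "counts": list(acc_frac)},
        "exact_ci_95": [lo, hi],
        "per_class_accuracy": {
            g: {"fraction": v[0], "counts": list(v[1])} for g, v in per_class.items()
        },
        "binary_grade0_positive": {
            name: {"fraction": getattr(binary, name), "counts": list(binary.fractions[name])}
            for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy")
        },
    }


def synthetic_olo_accuracy(
    seed: int,
    permute_labels: bool = False,
    n_patients_per_grade: tuple[int, int, int] = (6, 6, 6),
    wells_per_patient: int = 16,
    arms: tuple[str, ...] = ("cisplatin",),
    network: NetworkConfig | None = None,
) -> float:
    """One-left-out three-class accuracy on a fresh synthetic cohort.

    The study-condition defaults are a 6/6/6 cohort with 16 replicate wells
    and the strong-effect phenotypes. ``permute_labels=True`` shuffles the
    truth grades before validation (the label-permutation null: accuracy
    should drop to chance, 1/3).
    """
    spec = CohortSpec(
        n_patients_per_grade=n_patients_per_grade,
        wells_per_patient=wells_per_patient,
        arms=arms,
        seed=stage_seed(seed, "simulate"),
    )
    cohort = generate_cohort(spec, AcquisitionConfig(), default_phenotypes())
    candidates = cohort_candidates(cohort)
    truths = pd.Series(cohort.grades.set_index("patient_id")["grade"], dtype=str)
    if permute_labels:
        rng = np.random.default_rng(stage_seed(seed, "permute"))
        truths = pd.Series(rng.permutation(truths.to_numpy()), index=truths.index)
    net = network or NetworkConfig()
    net = dataclasses.replace(net, seed=stage_seed(seed, "olo"))
    predictions = olo_cross_validate(candidates, truths, net)
    return float((predictions["predicted"] == predictions["actual"]).mean())


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full synthetic pipeline and write all artifacts.

    Stages: simulate → candidate features → OLO classification → evaluation.
    A stage failure is recorded in the manifest and downstream stages are
    skipped. Returns the manifest (also written to ``<outdir>/manifest.json``).
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.snapshot(),
        version=__version__,
        started_utc=time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
    )
    manifest_path = outdir / "manifest.json"

    try:
        log.info("simulate: cohort %s, wells=%d, arms=%s",
                 config.n_patients_per_grade, config.wells_per_patient, config.arms)
        spec = CohortSpec(
            n_patients_per_grade=tuple(config.n_patients_per_grade),
            wells_per_patient=config.wells_per_patient,
            arms=tuple(config.arms),
            seed=stage_seed(config.seed, "simulate"),
        )
        cohort = generate_cohort(spec, config.acquisition, default_phenotypes())
        grades_path = outdir / "grades.csv"
        write_outcomes(cohort.grades, grades_path)
        outputs = {"grades": grades_path}
        if config.write_cohort_h5:
            cohort_path = outdir / "cohort.h5"
            write_cohort(cohort, cohort_path)
            outputs["cohort"] = cohort_path
        manifest.add_stage("simulate", outputs)
    except Exception:
        manifest.stages["simulate"] = {"status": "failed", "outputs": {}}
        manifest.write(manifest_path)
        raise

    try:
        log.info("features: computing candidate biomarker panel")
        candidates = cohort_candidates(
            cohort, config.floor_fraction, config.inhibition_threshold
        )
        features_path = outdir / "features.csv"
        candidates.to_csv(features_path, index_label="patient_id", float_format="%.12g")
        manifest.add_stage("features", {"features": features_path})
    except Exception:
        manifest.stages["features"] = {"status": "failed", "outputs": {}}
        manifest.write(manifest_path)
        raise

    try:
        log.info("olo: one-left-out classification of %d patients", len(candidates))
        net = dataclasses.replace(config.network, seed=stage_seed(config.seed, "olo"))
        truths = pd.Series(
            cohort.grades.set_index("patient_id")["grade"], dtype=str
        )
        predictions = olo_cross_validate(
            candidates, truths, net, k_features=config.k_features
        )
        pred_path = outdir / "predictions.csv"
        predictions.to_csv(pred_path, index=False, float_format="%.12g")
        selection_path = outdir / "selection.csv"
        _, _, report = select_biomarkers(candidates, truths, config.k_features)
        report.to_csv(selection_path, index=False, float_format="%.12g")
        manifest.add_stage("olo", {"predictions": pred_path, "selection": selection_path})
    except Exception:
        manifest.stages["olo"] = {"status": "failed", "outputs": {}}
        manifest.write(manifest_path)
        raise

    try:
        metrics = evaluate_predictions(predictions, truths)
        metrics_path = outdir / "metrics.json"
        metrics_path.write_text(json.dumps(metrics, indent=2) + "\n")
        manifest.add_stage("evaluate", {"metrics": metrics_path})
    except Exception:
        manifest.stages["evaluate"] = {"status": "failed", "outputs": {}}
        manifest.write(manifest_path)
        raise

    manifest.write(manifest_path)
    log.info("run complete: %s", outdir)
    return manifest
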