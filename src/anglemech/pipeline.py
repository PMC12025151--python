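"""End-to-end orchestration: reproducible runs over all pipeline stages.

Stages (in dependency order): ``simulate`` renders a synthetic cohort,
``features`` extracts biometric feature rows from masks, ``train`` fits and
selects the three mechanism classifiers, ``assess`` produces per-image
integrated assessments, ``evaluate`` scores them against the labels.  A run
is reconstructible from its config and seed alone: every artifact directory
carries a manifest with the config hash, seed and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    ALGORITHM_ORDER,
    LabeledDataset,
    Mechanism,
    TrainedModel,
    predict_probabilities,
    select_best_model,
    split_dataset,
    train_model,
)
from .features import FEATURE_COLUMNS, extract_feature_row
from .geometry import AcquisitionMode, AngleMechError, read_mask, write_mask
from .integrate import IntegratedClass, assess_image, integrate
from .metrics import binary_metrics, cohens_kappa, confusion, multiclass_accuracy, roc_auc
from .synthetic import CohortSpec, sample_cohort

__all__ = ["RunConfig", "DependencyError", "run_pipeline", "run_benchmark",
           "parameter_recovery_grid", "STAGES"]

log = logging.getLogger("anglemech")

STAGES = ("simulate", "features", "train", "assess", "evaluate", "all")


class DependencyError(AngleMechError):
    pass


@dataclass
class RunConfig:
    """Single source of truth for a pipeline run (YAML-loadable)."""

    out_dir: str = "run"
    seed: int = 0
    n_images: int = 400
    class_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    mode: str = AcquisitionMode.HALF_FRAME.value
    boundary_jitter_px: float = 0.5
    palette: dict = field(default_factory=lambda: {0: 0, 1: 1, 2: 2, 3: 3})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n=self.n_images,
            class_weights=tuple(self.class_weights),
            seed=self.seed,
            mode=AcquisitionMode(self.mode),
            boundary_jitter_px=self.boundary_jitter_px,
        )


def _manifest(cfg: RunConfig, stage: str) -> dict:
    return {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
    }


def _write_manifest(cfg: RunConfig, stage: str, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / f"manifest_{stage}.json").write_text(json.dumps(_manifest(cfg, stage), indent=2))


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise DependencyError(f"missing artifact {path}; run stage '{producer}' first")
    return path


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    masks_dir = out / "masks"
    masks_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    cohort = sample_cohort(cfg.cohort_spec())
    for mask, (_, rec) in zip(cohort.masks, cohort.table.iterrows()):
        write_mask(mask, masks_dir / f"{rec.image_id}.png", palette=cfg.palette)
    cohort.table.to_csv(out / "labels.csv", index=False)
    gt_rows = []
    for gt, (_, rec) in zip(cohort.ground_truths, cohort.table.iterrows()):
        gt_rows.append(
            {
                "image_id": rec.image_id,
                "spur_row": gt.spur.row,
                "spur_col": gt.spur.col,
                "it_spur500_um": gt.it_spur500_um,
                "it_spur750_um": gt.it_spur750_um,
                "it_root500_um": gt.it_root500_um,
                "sagitta_um": gt.sagitta_um,
                "contact_ratio": gt.contact_ratio,
            }
        )
    pd.DataFrame(gt_rows).to_csv(out / "ground_truth.csv", index=False)
    _write_manifest(cfg, "simulate", out)
    log.info("simulate: %d masks in %.1fs", len(cohort.masks), time.perf_counter() - t0)
    return out


def stage_features(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    masks_dir = _require(out / "masks", "simulate")
    t0 = time.perf_counter()
    rows = []
    for png in sorted(masks_dir.glob("*.png")):
        mask = read_mask(png, palette=cfg.palette)
        rows.append(extract_feature_row(mask, image_id=png.stem).to_dict())
    pd.DataFrame(rows).to_csv(out / "features.csv", index=False)
    _write_manifest(cfg, "features", out)
    log.info("features: %d rows in %.1fs", len(rows), time.perf_counter() - t0)
    return out


def _datasets(features: pd.DataFrame, labels: pd.DataFrame) -> dict[Mechanism, LabeledDataset]:
    merged = features.merge(labels, on="image_id", validate="one_to_one")
    return {
        mech: LabeledDataset(
            features=merged,
            labels=merged[mech.value].to_numpy(bool),
            patient_ids=merged["patient_id"].to_numpy(),
        )
        for mech in Mechanism
    }


def train_and_select(
    ds: LabeledDataset, target: Mechanism, seed: int
) -> tuple[TrainedModel, dict]:
    """3:1 patient-grouped split, fit the five-family bank, select by MCC.

    Returns the selected model plus its held-out metric report."""
    train, test = split_dataset(ds, seed)
    candidates = [train_model(train, algo, target, seed=seed) for algo in ALGORITHM_ORDER]
    best = select_best_model(candidates, test)
    probs = predict_probabilities(best, test)
    pred = probs >= best.threshold
    rep = binary_metrics(confusion(test.labels, pred))
    report = rep.as_dict()
    try:
        report["auc"], _ = roc_auc(probs, test.labels)
    except AngleMechError:
        report["auc"] = float("nan")  # single-class held-out set
    report["algorithm"] = best.algorithm.value
    report["n_train"] = len(train)
    report["n_test"] = len(test)
    return best, report


def stage_train(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    features = pd.read_csv(_require(out / "features.csv", "features"))
    labels = pd.read_csv(_require(out / "labels.csv", "simulate"))
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    summary = {}
    for mech, ds in _datasets(features, labels).items():
        best, report = train_and_select(ds, mech, cfg.seed)
        best.save(models_dir / f"{mech.value}.json")
        summary[mech.value] = report
    (out / "training_report.json").write_text(json.dumps(summary, indent=2, default=float))
    _write_manifest(cfg, "train", out)
    log.info("train: selected %s", {k: v["algorithm"] for k, v in summary.items()})
    return out


def stage_assess(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    masks_dir = _require(out / "masks", "simulate")
    models_dir = _require(out / "models", "train")
    bundle = {m: TrainedModel.load(models_dir / f"{m.value}.json") for m in Mechanism}
    records = []
    for png in sorted(masks_dir.glob("*.png")):
        mask = read_mask(png, palette=cfg.palette)
        records.append(assess_image(mask, bundle, image_id=png.stem).to_dict())
    pd.DataFrame(records).to_csv(out / "assessments.csv", index=False)
    _write_manifest(cfg, "assess", out)
    log.info("assess: %d records", len(records))
    return out


def stage_evaluate(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    calls = pd.read_csv(_require(out / "assessments.csv", "assess"))
    labels = pd.read_csv(_require(out / "labels.csv", "simulate"))
    merged = calls.merge(labels, on="image_id", suffixes=("_pred", "_true"),
                         validate="one_to_one")
    report: dict = {}
    for mech in Mechanism:
        y_true = merged[f"{mech.value}_true"].to_numpy(bool)
        y_pred = merged[f"{mech.value}_pred"].to_numpy(bool)
        rep = binary_metrics(confusion(y_true, y_pred)).as_dict()
        try:
            rep["auc"], _ = roc_auc(merged[f"p_{mech.value}"].to_numpy(float), y_true)
        except AngleMechError:
            pass
        report[mech.value] = rep
    acc, table = multiclass_accuracy(
        merged["integrated_class_true"], merged["integrated_class_pred"],
        classes=[c.value for c in IntegratedClass],
    )
    report["integrated"] = {
        "accuracy": acc,
        "kappa": cohens_kappa(merged["integrated_class_true"], merged["integrated_class_pred"]),
        "confusion": table.tolist(),
        "classes": [c.value for c in IntegratedClass],
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    _write_manifest(cfg, "evaluate", out)
    log.info("evaluate: integrated accuracy %.3f", acc)
    return out


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "features": stage_features,
    "train": stage_train,
    "assess": stage_assess,
    "evaluate": stage_evaluate,
}


def run_pipeline(cfg: RunConfig, stage: str = "all") -> Path:
    """Execute one stage (or ``all``, in dependency order)."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    if not logging.getLogger().handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                            format="%(asctime)s %(name)s %(levelname)s %(message)s")
    names = list(_STAGE_FUNCS) if stage == "all" else [stage]
    out = Path(cfg.out_dir)
    for name in names:
        _STAGE_FUNCS[name](cfg)
    return out


def parameter_recovery_grid(seed: int = 0) -> pd.DataFrame:
    """Measured-vs-analytic errors over a 100-mask synthetic parameter grid.

    The grid spans root thickness 300-600 um, posterior sagitta -100-400 um
    and ciliary contact fraction 0-1 (5 x 5 x 4 combinations); one row per
    mask with absolute thickness errors, relative sagitta error, contact
    ratio error and spur localization error in pixels.
    """
    import itertools

    from .synthetic import AnatomyParams, render_mask

    rng = np.random.default_rng(seed)
    rows = []
    for tr, sag, f in itertools.product(
        np.linspace(300, 600, 5), np.linspace(-100, 400, 5), np.linspace(0, 1, 4)
    ):
        params = AnatomyParams(
            iris_thickness_root_um=float(tr),
            iris_thickness_pupil_um=float(max(250.0, tr - 120.0)),
            bowing_sagitta_um=float(sag),
            ciliary_contact_fraction=float(f),
        )
        mask, gt = render_mask(params, seed=int(rng.integers(0, 2**31 - 1)))
        d = extract_feature_row(mask).to_dict()
        rows.append(
            {
                "it_spur500_err_um": abs(d["it_spur500_um"] - gt.it_spur500_um),
                "it_spur750_err_um": abs(d["it_spur750_um"] - gt.it_spur750_um),
                "it_root500_err_um": abs(d["it_root500_um"] - gt.it_root500_um),
                "sagitta_rel_err": (
                    abs(d["iris_curvature_um"] - gt.sagitta_um) / abs(gt.sagitta_um)
                    if abs(gt.sagitta_um) > 1.0
                    else np.nan
                ),
                "contact_ratio_err": abs(d["contact_ratio"] - gt.contact_ratio),
                "spur_err_px": float(
                    np.hypot(d["spur_row"] - gt.spur.row, d["spur_col"] - gt.spur.col)
                ),
                "pitch_um": max(mask.spacing.um_per_px_x, mask.spacing.um_per_px_y),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# in-memory end-to-end benchmark (used by the test suite and the acceptance
# script; avoids disk round-trips)

def run_benchmark(n: int = 400, seed: int = 0, jitter_px: float = 0.5) -> dict:
    """Render a cohort, extract features, train/select, and score everything.

    Returns a dictionary with per-mechanism held-out reports, the integrated
    four-class accuracy on the pooled held-out images, and parameter-recovery
    summaries against the generator's analytic ground truth.
    """
    spec = CohortSpec(n=n, seed=seed, boundary_jitter_px=jitter_px)
    cohort = sample_cohort(spec)
    feats, spur_err_px = [], []
    for mask, gt, (_, rec) in zip(cohort.masks, cohort.ground_truths,
                                  cohort.table.iterrows()):
        row = extract_feature_row(mask, image_id=rec.image_id)
        feats.append(row.to_dict())
        spur_err_px.append(
            float(np.hypot(row.spur.point.row - gt.spur.row, row.spur.point.col - gt.spur.col))
        )
    features = pd.DataFrame(feats)

    results: dict = {"n": n, "seed": seed, "mechanisms": {}}
    results["spur_error_px"] = spur_err_px
    bundle: dict[Mechanism, TrainedModel] = {}
    test_sets: dict[Mechanism, LabeledDataset] = {}
    for mech, ds in _datasets(features, cohort.table).items():
        best, report = train_and_select(ds, mech, seed)
        bundle[mech] = best
        train, test = split_dataset(ds, seed)
        test_sets[mech] = test
        results["mechanisms"][mech.value] = report

    # integrated assessment on the (shared) held-out images
    test_ids = set(test_sets[Mechanism.PB].features["image_id"])
    merged = features.merge(cohort.table, on="image_id")
    held = merged[merged["image_id"].isin(test_ids)]
    y_true, y_pred = [], []
    for _, row in held.iterrows():
        calls = {m: predict_probabilities(bundle[m], LabeledDataset(
            features=row.to_frame().T, labels=[row[m.value]], patient_ids=[row["patient_id"]],
        ))[0] >= bundle[m].threshold for m in Mechanism}
        y_pred.append(integrate(calls[Mechanism.PB], calls[Mechanism.TPI],
                                calls[Mechanism.ALCB]).value)
        y_true.append(row["integrated_class"])
    acc, table = multiclass_accuracy(np.array(y_true), np.array(y_pred),
                                     classes=[c.value for c in IntegratedClass])
    results["integrated"] = {"accuracy": acc, "confusion": table.tolist(),
                             "n_test": len(y_true)}
    results["features"] = features
    results["cohort_table"] = cohort.table
    return results
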