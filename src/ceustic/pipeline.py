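"""End-to-end orchestration: video + clinical record -> diagnosis report.

Three workflows compose the library modules:

* :func:`run_predict` — one investigation through segmentation, TIC
  extraction and the classifier, writing the per-second curve CSV, the
  TIC-parameter CSV and a five-class probability report;
* :func:`run_build_dataset` — many investigations into one feature table
  (8 feature columns + 5 one-hot label columns);
* :func:`run_train_eval` — train the classifier on such a table and emit
  the four-metric report for the training and validation splits plus the
  loss history.

Every workflow is deterministic under a fixed config seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import classifier as clf
from . import metrics as met
from .frame_io import DEFAULT_REGIONS, RegionSpec, read_video
from .segmentation import (
    GroundTruthMaskProvider,
    MaskProvider,
    UNetMaskProvider,
    load_unet,
)
from .synthetic import FEATURE_COLUMNS, LABEL_COLUMNS
from .tic import extract_params, sample_tic, smooth_tic, write_tic_csv

__all__ = [
    "PipelineConfig",
    "run_predict",
    "run_build_dataset",
    "run_train_eval",
    "make_mask_provider",
]

log = logging.getLogger("ceustic")

CLINICAL_FIELDS = FEATURE_COLUMNS[:4]  # Gender, Age, Cirrhosis History, Hepatitis History


@dataclass
class PipelineConfig:
    """Tunable pipeline settings; defaults mirror the acquisition protocol."""

    regions: dict[str, RegionSpec] = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    kernel_size: int = 10
    reject_fraction: float = 0.75
    filter_window: int = 51
    filter_polyorder: int = 3
    mask_provider: str = "ground_truth"  # or "unet"
    unet_checkpoint: str | None = None
    classifier_checkpoint: str | None = None
    output_dir: str = "."
    seed: int = 0
    frame_rate_override: float | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        regions = raw.pop("regions", None)
        cfg = cls(**raw)
        if regions:
            cfg.regions = {
                name: RegionSpec(name, *[int(v) for v in coords])
                for name, coords in regions.items()
            }
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["regions"] = {
            name: [r.x_min, r.x_max, r.y_min, r.y_max] for name, r in self.regions.items()
        }
        Path(path).write_text(yaml.safe_dump(data))


def make_mask_provider(cfg: PipelineConfig, video_path: str | Path) -> MaskProvider:
    """Build the configured mask provider for one investigation."""
    if cfg.mask_provider == "unet":
        if not cfg.unet_checkpoint:
            raise ValueError("mask_provider 'unet' requires unet_checkpoint")
        return UNetMaskProvider(load_unet(cfg.unet_checkpoint))
    if cfg.mask_provider == "ground_truth":
        mask_dir = Path(video_path) / "masks"
        if not mask_dir.is_dir():
            raise FileNotFoundError(
                f"ground-truth provider needs a masks/ directory next to the "
                f"frames in {video_path}"
            )
        from .frame_io import read_mask_png

        masks = np.stack(
            [read_mask_png(p) for p in sorted(mask_dir.glob("mask_*.png"))]
        )
        return GroundTruthMaskProvider(masks, cfg.regions["b_mode"])
    raise ValueError(f"unknown mask provider {cfg.mask_provider!r}")


def _validate_clinical(record: Mapping) -> dict[str, float]:
    missing = [k for k in CLINICAL_FIELDS if k not in record]
    if missing:
        raise ValueError(f"clinical record is missing field(s): {missing}")
    rec = {k: float(record[k]) for k in CLINICAL_FIELDS}
    if rec["Gender"] not in (1.0, 2.0):
        raise ValueError("Gender must be encoded 1 (male) or 2 (female)")
    for key in ("Cirrhosis History", "Hepatitis History"):
        if rec[key] not in (0.0, 1.0):
            raise ValueError(f"{key} must be 0 or 1")
    return rec


def _extract_features(video_path: str | Path, cfg: PipelineConfig, out_dir: Path | None):
    """Segment, sample and smooth the TIC for one video; return (params, curve)."""
    frames = read_video(video_path, cfg.frame_rate_override)
    provider = make_mask_provider(cfg, video_path)
    curve = sample_tic(
        frames,
        provider,
        regions=cfg.regions,
        kernel=cfg.kernel_size,
        reject_fraction=cfg.reject_fraction,
    )
    smoothed = smooth_tic(curve, cfg.filter_window, cfg.filter_polyorder)
    params = extract_params(smoothed, series="lesion")
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        write_tic_csv(smoothed, params, out_dir / "tic.csv")
    return params, smoothed


def run_predict(
    video_path: str | Path,
    clinical_record: Mapping,
    cfg: PipelineConfig,
    model: clf.TrainedModel | None = None,
) -> dict:
    """Classify one investigation; returns the per-class probability report."""
    rec = _validate_clinical(clinical_record)
    out_dir = Path(cfg.output_dir)
    log.info("predict: extracting TIC from %s", video_path)
    params, _ = _extract_features(video_path, cfg, out_dir)

    if model is None:
        if not cfg.classifier_checkpoint:
            raise ValueError("no trained classifier: pass model or set classifier_checkpoint")
        model = clf.load_model(cfg.classifier_checkpoint)

    features = np.array(
        [
            rec["Gender"], rec["Age"], rec["Cirrhosis History"], rec["Hepatitis History"],
            params.max_intensity, params.auc, params.mtt, params.ttp,
        ]
    )
    log.info("predict: running classifier")
    probs = clf.predict(model, features)
    report = clf.probability_report(probs)
    pd.DataFrame([report]).to_csv(out_dir / "prediction.csv", index=False)
    return {"probabilities": report, "tic_params": params.as_dict()}


def run_build_dataset(
    items: Sequence[tuple[str | Path, Mapping]],
    cfg: PipelineConfig,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Extract one feature row per (video, clinical record with label) pair.

    Records must carry the four clinical fields plus a ``label`` naming one
    of the five lesion classes.  Per-video failures are logged and skipped;
    the summary count is logged at the end.
    """
    if not items:
        raise ValueError("need at least one (video, record) pair")
    rows = []
    failures = 0
    for video_path, record in items:
        try:
            rec = _validate_clinical(record)
            label = record["label"]
            if label not in LABEL_COLUMNS:
                raise ValueError(f"unknown label {label!r}; expected one of {LABEL_COLUMNS}")
            params, _ = _extract_features(video_path, cfg, out_dir=None)
            row = {
                **{k: rec[k] for k in CLINICAL_FIELDS},
                "Maximum Intensity": params.max_intensity,
                "Area Under the Curve": params.auc,
                "Mean Transit Time": params.mtt,
                "Time to Peak": params.ttp,
            }
            for name in LABEL_COLUMNS:
                row[name] = int(name == label)
            rows.append(row)
        except Exception:
            failures += 1
            log.exception("build-dataset: skipping %s", video_path)
    log.info("build-dataset: %d rows extracted, %d failures", len(rows), failures)
    if not rows:
        raise RuntimeError("all videos failed feature extraction")
    df = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS) + list(LABEL_COLUMNS))
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df


def run_train_eval(
    dataset: pd.DataFrame | str | Path,
    cfg: PipelineConfig,
    train_config: clf.TrainConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, clf.TrainedModel]:
    """Train the classifier on a feature table and report the four metrics.

    Returns a two-row (Training / Validation) metrics table and the trained
    model; optionally writes ``metrics.csv``, ``loss_history.csv`` and the
    model checkpoint into ``out_dir``.
    """
    if not isinstance(dataset, pd.DataFrame):
        dataset = pd.read_csv(dataset)
    X, y = clf.dataset_from_frame(dataset)
    tcfg = train_config or clf.TrainConfig(seed=cfg.seed)
    model = clf.train_classifier(X, y, config=tcfg)

    X_tr, y_tr, X_va, y_va = clf.split_dataset(X, y, tcfg.split_fraction, tcfg.seed)
    rows = {}
    for name, Xs, ys in (("Training", X_tr, y_tr), ("Validation", X_va, y_va)):
        pred = model.predict_proba(Xs).argmax(axis=1)
        cm = met.confusion_matrix(ys, pred, n_classes=len(LABEL_COLUMNS))
        rows[name] = met.metrics_report(cm)
    report = met.report_frame(rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "metrics.csv")
        pd.DataFrame(model.history).to_csv(out / "loss_history.csv", index=False)
        clf.save_model(model, out / "classifier.npz")
    return report, model
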