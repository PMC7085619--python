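"""End-to-end pipeline: synth -> ingest -> QC -> features -> placement -> models.

A single :class:`PipelineConfig` (YAML-loadable) drives every stage; one
master seed fans out to per-stage seeds through a documented derivation, so
stages are independently reproducible and a rerun with the same config is
byte-identical in its persisted reports.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synth as _synth
from .features import (BandSpec, FeatureMatrix, binary_labels,
                       build_feature_matrix)
from .ingest import assemble_segments
from .metrics import confusion, loocv_error, performance
from .models import make_classifier
from .placement import rank_positions
from .preprocess import PreprocessConfig, make_uniform_segment, qc_filter
from .profiles import CLASS_IDS, POSITIONS

__all__ = ["ClassifierSettings", "PipelineConfig", "RunResult", "run_pipeline",
           "classification_report", "compare_feature_counts"]

_STAGE_SEEDS = {"synth": 1, "classify": 2, "compare": 3}


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    ss = np.random.SeedSequence([master & 0x7FFFFFFF, _STAGE_SEEDS.get(stage, 0)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class ClassifierSettings:
    """Shared settings for the four classifier families."""

    kinds: tuple[str, ...] = ("svm", "bayes", "knn", "nn")
    nn_hidden: int = 10
    nn_epochs: int = 150
    nn_lr: float = 1.0
    knn_k: int = 5
    svm_c: float = 1.0
    cross_validate: bool = True

    def build(self, kind: str, seed: int):
        if kind == "nn":
            return make_classifier("nn", hidden=self.nn_hidden,
                                   epochs=self.nn_epochs, lr=self.nn_lr, seed=seed)
        if kind == "knn":
            return make_classifier("knn", k=self.knn_k)
        if kind == "svm":
            return make_classifier("svm", C=self.svm_c)
        return make_classifier(kind)


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration of a full run."""

    out_dir: str = "runs/cyclesense"
    seed: int = 0
    synth: _synth.SynthConfig = field(default_factory=_synth.default_config)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    band_edges: tuple[float, ...] = (0.0, 3.0, 8.0, 15.0, 30.0)
    slope_steep_pct: float = 15.0
    task: str = "AB"
    feature_subset: tuple[str, ...] = ("F3_8", "F8_15")
    placement_class_pair: tuple[str, str] = ("c3", "c4")
    placement_feature_pairs: tuple[tuple[str, str], ...] = (
        ("F0_3", "HR"), ("F3_8", "F15_30"))
    classifiers: ClassifierSettings = field(default_factory=ClassifierSettings)

    def __post_init__(self) -> None:
        if self.task not in ("AB", "4class"):
            raise ValueError(f"task must be 'AB' or '4class', got {self.task!r}")
        BandSpec(self.band_edges)
        names = ("F0_3", "F3_8", "F8_15", "F15_30", "HR")
        for f in self.feature_subset:
            if f not in names:
                raise ValueError(f"unknown feature {f!r}")
        for pair in self.placement_feature_pairs:
            for f in pair:
                if f not in names:
                    raise ValueError(f"unknown feature {f!r}")
        for c in self.placement_class_pair:
            if c not in CLASS_IDS:
                raise ValueError(f"unknown class {c!r}")
        unknown = set(self.synth.positions) - set(POSITIONS)
        if unknown:
            raise ValueError(f"unknown positions {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kw = dict(raw)
        if "synth" in kw:
            s = dict(kw["synth"])
            if "positions" in s:
                s["positions"] = tuple(s["positions"])
            if "preprocess" in s:
                s["preprocess"] = PreprocessConfig(**s["preprocess"])
            kw["synth"] = _synth.SynthConfig(**s)
        if "preprocess" in kw:
            kw["preprocess"] = PreprocessConfig(**kw["preprocess"])
        if "classifiers" in kw:
            c = dict(kw["classifiers"])
            if "kinds" in c:
                c["kinds"] = tuple(c["kinds"])
            kw["classifiers"] = ClassifierSettings(**c)
        for key in ("band_edges", "feature_subset", "placement_class_pair"):
            if key in kw:
                kw[key] = tuple(kw[key])
        if "placement_feature_pairs" in kw:
            kw["placement_feature_pairs"] = tuple(
                tuple(p) for p in kw["placement_feature_pairs"])
        return cls(**kw)


@dataclass
class RunResult:
    """Artifacts and bookkeeping of one pipeline run."""

    run_dir: Path
    n_read: int
    n_rejected: int
    n_featured: int
    feature_matrix: FeatureMatrix | None
    placement: pd.DataFrame | None
    metrics: pd.DataFrame | None
    log_lines: list[str]


def classification_report(
    fm: FeatureMatrix,
    settings: ClassifierSettings,
    *,
    task: str = "AB",
    feature_subset: tuple[str, ...] = ("F3_8", "F8_15"),
    positions: list[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-position, per-model accuracy / CV table.

    Resubstitution accuracy, specificity/sensitivity/F1 (binary task, class
    A positive) and, when enabled, the leave-one-out error.
    """
    positions = positions or sorted(set(fm.positions.tolist()))
    rows = []
    for pos in positions:
        sub = fm.select(positions=[pos], features=list(feature_subset))
        y = binary_labels(sub.targets) if task == "AB" else sub.targets
        X = sub.X
        for kind in settings.kinds:
            if kind == "svm" and np.unique(y).size != 2:
                continue  # the linear SVM is binary-only
            model = settings.build(kind, seed)
            model.fit(X, y)
            pred = model.predict(X)
            row = {
                "position": pos,
                "model": kind,
                "n": int(X.shape[0]),
                "features": "+".join(feature_subset),
                "acc_resub": float(np.mean(pred == y)),
            }
            if task == "AB":
                rep = performance(confusion(y, pred, positive="A"))
                row.update(tnr=rep.sp, tpr=rep.se, f1s=rep.f1s)
            if settings.cross_validate:
                res = loocv_error(lambda: settings.build(kind, seed), X, y)
                row["cv_error"] = res.error
                row["acc_loocv"] = res.accuracy
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    *,
    stages: tuple[str, ...] = ("synth", "ingest", "qc", "features",
                               "placement", "classify"),
    keep_raw: bool = False,
) -> RunResult:
    """Run the configured pipeline and persist each stage's outputs.

    Every stage logs its bookkeeping (segments read, rejected, featured).
    The raw synthetic dataset is written under ``<out_dir>/data`` and
    removed afterwards unless ``keep_raw`` is set.
    """
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    fm = None
    placement_df = None
    metrics_df = None
    n_read = n_rej = n_feat = 0

    data_dir = run_dir / "data"
    synth_cfg = dataclasses.replace(
        config.synth, seed=stage_seed(config.seed, "synth"),
        preprocess=config.preprocess)
    try:
        if "synth" in stages:
            paths = _synth.gen_dataset(synth_cfg, data_dir)
            log.append(f"synth: wrote {len(pd.read_csv(paths.manifest))} segments")
        if "ingest" in stages:
            assembled = assemble_segments(data_dir / "manifest.csv", data_dir,
                                          data_dir / "track.csv")
            n_read = len(assembled.segments) + len(assembled.problems)
            log.append(f"ingest: read {n_read} segments "
                       f"({len(assembled.problems)} unusable)")
            segments = assembled.segments
        if "qc" in stages:
            qc = qc_filter(segments, alpha=config.preprocess.qc_alpha)
            n_rej = len(qc.rejected)
            log.append(f"qc: rejected {n_rej} of {qc.n_total} "
                       f"({100.0 * n_rej / max(qc.n_total, 1):.1f}%)")
            segments = qc.kept
        if "features" in stages:
            uniform = [make_uniform_segment(s, config.preprocess) for s in segments]
            fm = build_feature_matrix(uniform, BandSpec(config.band_edges))
            n_feat = fm.Q
            log.append(f"features: {n_feat} segments featured")
            fm.to_frame().to_csv(run_dir / "features.csv", index=False,
                                 float_format="%.8f")
        if "placement" in stages and fm is not None:
            frames = []
            for pair in config.placement_feature_pairs:
                ranking = rank_positions(fm, config.placement_class_pair, pair)
                frames.append(pd.DataFrame([{
                    "rank": i + 1,
                    "position": r.position,
                    "features": "+".join(pair),
                    "classes": "+".join(config.placement_class_pair),
                    "Z": r.Z, "D": r.D, "ST": r.ST,
                } for i, r in enumerate(ranking)]))
            placement_df = pd.concat(frames, ignore_index=True)
            placement_df.to_csv(run_dir / "placement.csv", index=False,
                                float_format="%.6f")
            best = placement_df.loc[placement_df["rank"] == 1, "position"].tolist()
            log.append(f"placement: top position per feature pair: {best}")
        if "classify" in stages and fm is not None:
            metrics_df = classification_report(
                fm, config.classifiers, task=config.task,
                feature_subset=config.feature_subset,
                seed=stage_seed(config.seed, "classify"),
            )
            metrics_df.to_csv(run_dir / "metrics.csv", index=False,
                              float_format="%.6f")
            log.append(f"classify: {len(metrics_df)} (position, model) rows")
    except Exception as exc:
        stage = log[-1].split(":")[0] if log else "start"
        raise RuntimeError(f"pipeline failed after stage '{stage}': {exc}") from exc
    finally:
        if not keep_raw and data_dir.exists():
            import shutil
            shutil.rmtree(data_dir, ignore_errors=True)

    (run_dir / "log.txt").write_text("\n".join(log) + "\n")
    return RunResult(run_dir=run_dir, n_read=n_read, n_rejected=n_rej,
                     n_featured=n_feat, feature_matrix=fm,
                     placement=placement_df, metrics=metrics_df, log_lines=log)


def compare_feature_counts(
    fm: FeatureMatrix,
    settings: ClassifierSettings | None = None,
    *,
    two_features: tuple[str, str] = ("F3_8", "F8_15"),
    seed: int = 0,
) -> pd.DataFrame:
    """Neural-network accuracy / CV error with 2 vs 5 features, per position.

    Returns one row per position with the paired metrics and their deltas
    (positive ``delta_acc`` means the 5-feature model is more accurate).
    """
    settings = settings or ClassifierSettings(kinds=("nn",))
    all_features = fm.feature_names
    rep2 = classification_report(fm, dataclasses.replace(settings, kinds=("nn",)),
                                 feature_subset=tuple(two_features), seed=seed)
    rep5 = classification_report(fm, dataclasses.replace(settings, kinds=("nn",)),
                                 feature_subset=tuple(all_features), seed=seed)
    merged = rep2.merge(rep5, on="position", suffixes=("_2f", "_5f"))
    out = pd.DataFrame({
        "position": merged["position"],
        "acc_2f": merged["acc_loocv_2f" if settings.cross_validate else "acc_resub_2f"],
        "acc_5f": merged["acc_loocv_5f" if settings.cross_validate else "acc_resub_5f"],
    })
    if settings.cross_validate:
        out["cv_2f"] = merged["cv_error_2f"]
        out["cv_5f"] = merged["cv_error_5f"]
        out["delta_cv"] = out["cv_5f"] - out["cv_2f"]
    out["delta_acc"] = out["acc_5f"] - out["acc_2f"]
    return out
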