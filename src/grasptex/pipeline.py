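"""End-to-end grasp-classification pipeline as model/results objects.

:class:`GraspModel` binds a labeled dataset to a
:class:`PipelineConfig`; :meth:`GraspModel.fit` runs the full chain —
channel concatenation, multi-parameter wavelet decomposition, per-source
texture + statistical features, min–max normalisation, loss-driven
subband ranking, top-k merge, iterative NCA selection, and final
cross-validated classification — returning a :class:`GraspResults`
carrying every intermediate artifact and a ``summary()`` table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from . import stats
from .classify import ClassifierSpec, EvaluationReport, crossval_predict, evaluation_report
from .data import Dataset
from .inca import DEFAULT_SIZE_RANGE, INCAResult, inca_select
from .selection import (
    LossTable,
    MergedFeatures,
    extract_features,
    minmax_normalize,
    select_and_merge,
    vector_losses,
)
from .tqwt import DEFAULT_PARAMS, TQWTParams

__all__ = ["PipelineConfig", "GraspModel", "GraspResults", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """All tunable parameters; the defaults reproduce the published setup."""

    tqwt_params: tuple[TQWTParams, ...] = DEFAULT_PARAMS
    top_k: int = 20
    inca_range: tuple[int, int] = DEFAULT_SIZE_RANGE
    inca_stride: int = 1
    nca_iter: int = 100
    folds: int = 10
    seed: int = 0
    classifier: str = "auto"  # "auto" | "kNN" | "SVM"
    per_matrix_normalization: bool = False
    sure_eps: float = stats.DEFAULT_SURE_EPS
    higuchi_kmax: int = stats.DEFAULT_HIGUCHI_KMAX

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tqwt_params"] = [
            {"Q": p.Q, "r": p.r, "J": p.J} for p in self.tqwt_params
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "tqwt_params" in d:
            d["tqwt_params"] = tuple(
                TQWTParams(p["Q"], p["r"], p["J"]) for p in d["tqwt_params"]
            )
        for key in ("inca_range",):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclasses.dataclass
class GraspResults:
    """Everything the fitted pipeline produced."""

    config: PipelineConfig
    dataset_name: str
    n_trials: int
    loss_table: LossTable
    merged: MergedFeatures
    inca: INCAResult
    classifier: ClassifierSpec
    predictions: np.ndarray  # predicted class names, out-of-fold
    report: EvaluationReport

    def summary(self) -> str:
        lines = [
            "Grasp-classification pipeline results",
            "=" * 38,
            f"Dataset:            {self.dataset_name} ({self.n_trials} trials)",
            f"Sources scored:     {self.loss_table.losses.shape[0]}",
            f"Loss classifier:    {self.loss_table.chosen_classifier}"
            f" (mean loss kNN={self.loss_table.losses[:, 0].mean():.4f},"
            f" SVM={self.loss_table.losses[:, 1].mean():.4f})",
            f"Merged sources:     {len(self.merged.selected_sources)}"
            f" -> {self.merged.matrix.shape[1]} features",
            f"Selected features:  {self.inca.selected_size}"
            f" (CV loss {self.inca.selected_loss:.4f})",
            f"Final classifier:   {self.classifier.family}",
            f"Accuracy:           {self.report.accuracy:.2f}%",
            f"Macro precision:    {self.report.macro_precision:.2f}%",
            f"Macro F1:           {self.report.macro_f1:.2f}%",
            "",
            self.report.to_text(),
        ]
        return "\n".join(lines)

    def save_artifacts(self, outdir: str | Path) -> list[Path]:
        """Write deterministic artifacts (CSV/JSON/text) to a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []

        def _write(name: str, text: str) -> None:
            path = outdir / name
            path.write_text(text)
            written.append(path)

        _write("config.json", json.dumps(self.config.to_dict(), indent=2, sort_keys=True))
        _write(
            "loss_table.csv",
            self.loss_table.to_frame().to_csv(index=False, float_format="%.10g"),
        )
        _write(
            "selected_sources.json",
            json.dumps(
                {
                    "selected_sources": self.merged.selected_sources,
                    "chosen_classifier": self.loss_table.chosen_classifier,
                },
                indent=2,
                sort_keys=True,
            ),
        )
        _write(
            "merged_provenance.csv",
            "column,source_id,within_source_index\n"
            + "\n".join(
                f"{i},{s},{j}" for i, (s, j) in enumerate(self.merged.provenance)
            )
            + "\n",
        )
        _write(
            "inca_result.json",
            json.dumps(
                {
                    "selected_size": self.inca.selected_size,
                    "selected_loss": self.inca.selected_loss,
                    "sizes": self.inca.sizes.tolist(),
                    "loss_curve": self.inca.loss_curve.tolist(),
                    "selected_indices": self.inca.selected_indices.tolist(),
                },
                indent=2,
                sort_keys=True,
            ),
        )
        _write("report.json", self.report.to_json())
        _write("confusion.txt", self.report.to_text() + "\n")
        _write("summary.txt", self.summary() + "\n")
        return written


class GraspModel:
    """The hand-crafted learning network bound to one labeled dataset."""

    def __init__(self, dataset: Dataset, config: PipelineConfig | None = None):
        self.dataset = dataset
        self.config = config or PipelineConfig()
        counts = dataset.class_counts()
        present = {c: n for c, n in counts.items() if n}
        if len(present) < 2:
            raise ValueError("dataset must contain at least two classes")
        if min(present.values()) < self.config.folds:
            raise ValueError(
                f"smallest class has {min(present.values())} trials "
                f"< folds={self.config.folds}"
            )

    @classmethod
    def from_dataframe(cls, frame, fs: float = 500.0, config: PipelineConfig | None = None):
        """Build from a DataFrame with columns ``label``, ``channel`` and samples."""
        from .data import Dataset as _DS
        from .data import GraspClass, SignalRecord

        records = []
        grouped = list(frame.groupby(frame.index // 2, sort=False))
        for _, pair in grouped:
            if len(pair) != 2:
                raise ValueError("expected channel-1/channel-2 row pairs")
            r1, r2 = pair.iloc[0], pair.iloc[1]
            samples1 = r1.drop(labels=["label", "channel"]).to_numpy(dtype=float)
            samples2 = r2.drop(labels=["label", "channel"]).to_numpy(dtype=float)
            records.append(SignalRecord(samples1, samples2, fs, GraspClass[r1["label"]]))
        return cls(_DS(records, name="dataframe"), config)

    def fit(self, features: np.ndarray | None = None) -> GraspResults:
        """Run the pipeline; pass a precomputed feature tensor to skip extraction."""
        cfg = self.config
        labels = np.array([r.label.name for r in self.dataset])

        logger.info("extracting per-source features for %d trials", len(self.dataset))
        if features is None:
            features = extract_features(
                self.dataset,
                cfg.tqwt_params,
                sure_eps=cfg.sure_eps,
                higuchi_kmax=cfg.higuchi_kmax,
            )
        n_trials, n_src, n_feat = features.shape
        logger.info("feature tensor: %d trials x %d sources x %d features", *features.shape)

        normalized = [
            minmax_normalize(features[:, s, :], per_matrix=cfg.per_matrix_normalization)
            for s in range(n_src)
        ]

        logger.info("scoring %d sources by %d-fold CV loss", n_src, cfg.folds)
        loss_table = vector_losses(normalized, labels, folds=cfg.folds, seed=cfg.seed)
        merged = select_and_merge(normalized, loss_table, top=cfg.top_k)
        logger.info(
            "top-%d sources %s merged -> %d columns",
            cfg.top_k,
            merged.selected_sources,
            merged.matrix.shape[1],
        )

        family = (
            loss_table.chosen_classifier if cfg.classifier == "auto" else cfg.classifier
        )
        spec = ClassifierSpec(family)

        logger.info("INCA sweep over sizes %s with %s", cfg.inca_range, family)
        inca = inca_select(
            merged.matrix,
            labels,
            size_range=cfg.inca_range,
            classifier=spec,
            folds=cfg.folds,
            seed=cfg.seed,
            stride=cfg.inca_stride,
            nca_iter=cfg.nca_iter,
        )
        logger.info("selected %d features (loss %.4f)", inca.selected_size, inca.selected_loss)

        X_final = merged.matrix[:, inca.selected_indices]
        predictions = crossval_predict(X_final, labels, spec, folds=cfg.folds, seed=cfg.seed)
        report = evaluation_report(labels, predictions)
        logger.info("final accuracy %.2f%%", report.accuracy)

        return GraspResults(
            config=cfg,
            dataset_name=self.dataset.name,
            n_trials=n_trials,
            loss_table=loss_table,
            merged=merged,
            inca=inca,
            classifier=spec,
            predictions=predictions,
            report=report,
        )


def run_pipeline(
    dataset: Dataset,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> GraspResults:
    """Functional wrapper: fit the model and optionally write artifacts."""
    results = GraspModel(dataset, config).fit()
    if outdir is not None:
        results.save_artifacts(outdir)
    return results
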