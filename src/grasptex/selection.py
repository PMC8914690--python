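"""Per-source feature vectors, normalisation, and loss-driven subband selection.

Every trial yields 154 sources: the concatenated raw signal (source 0)
and the 153 wavelet subbands (sources 1..153). Each source produces a
414-component vector (384 texture + 30 statistical features). Sources
are ranked by the 10-fold cross-validated misclassification rate of a
shallow classifier trained on that source's features alone, and the
best ``top`` (default 20) sources are concatenated into the merged
feature matrix (414 * 20 = 8280 columns).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from . import frustum, stats
from .classify import ClassifierSpec, crossval_predict
from .data import Dataset, SignalRecord
from .tqwt import DEFAULT_PARAMS, multi_tqwt

__all__ = [
    "N_SOURCES",
    "VECTOR_LEN",
    "FeatureVectors",
    "LossTable",
    "MergedFeatures",
    "extract_all_feature_vectors",
    "extract_features",
    "minmax_normalize",
    "vector_losses",
    "select_and_merge",
]

logger = logging.getLogger(__name__)

_warned_short: set[tuple[int, int]] = set()

VECTOR_LEN = 414  # 384 texture + 30 statistical


def n_sources(params_list=DEFAULT_PARAMS) -> int:
    return 1 + sum(p.J + 1 for p in params_list)


N_SOURCES = n_sources()  # 154 with the default parameter sets


def _source_features(band: np.ndarray, sure_eps: float, higuchi_kmax: int) -> np.ndarray:
    if band.size < frustum.BLOCK_LEN:
        padded = np.concatenate([band, np.zeros(frustum.BLOCK_LEN - band.size)])
        fp = frustum.frustum_features(padded)
    else:
        fp = frustum.frustum_features(band)
    se = stats.statistical_features(band, sure_eps=sure_eps, higuchi_kmax=higuchi_kmax)
    return np.concatenate([fp, se])


def extract_all_feature_vectors(
    record: SignalRecord,
    params_list=DEFAULT_PARAMS,
    sure_eps: float = stats.DEFAULT_SURE_EPS,
    higuchi_kmax: int = stats.DEFAULT_HIGUCHI_KMAX,
) -> np.ndarray:
    """The (n_sources, 414) feature array for one trial.

    Row 0 comes from the concatenated raw signal, rows 1..153 from the
    wavelet subbands in decomposition order. Subbands shorter than 49
    samples (never the case on full-length recordings) are zero-padded
    to one texture window; the statistical half always uses the raw band.
    """
    signal = record.signal
    sources = [signal] + multi_tqwt(signal, params_list)
    short = sum(1 for s in sources if s.size < frustum.BLOCK_LEN)
    if short and (short, len(sources)) not in _warned_short:
        _warned_short.add((short, len(sources)))
        logger.warning(
            "%d of %d sources are shorter than %d samples; texture features "
            "computed on zero-padded bands",
            short,
            len(sources),
            frustum.BLOCK_LEN,
        )
    return np.vstack([_source_features(s, sure_eps, higuchi_kmax) for s in sources])


def extract_features(dataset: Dataset, params_list=DEFAULT_PARAMS, **kwargs) -> np.ndarray:
    """Feature tensor of shape (n_trials, n_sources, 414) for a dataset."""
    return np.stack(
        [extract_all_feature_vectors(rec, params_list, **kwargs) for rec in dataset]
    )


def minmax_normalize(matrix, per_matrix: bool = False) -> np.ndarray:
    """Min-max scale to [0, 1], per feature column (constant columns map to 0)."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two observations")
    if per_matrix:
        lo, hi = X.min(), X.max()
        span = hi - lo
        return (X - lo) / span if span > 0 else np.zeros_like(X)
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    out = X - lo
    nz = span > 0
    out[:, nz] /= span[nz]
    out[:, ~nz] = 0.0
    return out


@dataclasses.dataclass
class LossTable:
    """Cross-validated misclassification rate of every source, per family."""

    losses: np.ndarray  # (n_sources, 2): columns kNN, SVM
    chosen_classifier: str  # "kNN" or "SVM" — family with lower mean loss

    @property
    def chosen_losses(self) -> np.ndarray:
        return self.losses[:, 0 if self.chosen_classifier == "kNN" else 1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "source_id": np.arange(self.losses.shape[0]),
                "loss_knn": self.losses[:, 0],
                "loss_svm": self.losses[:, 1],
                "loss_chosen": self.chosen_losses,
            }
        )


@dataclasses.dataclass
class MergedFeatures:
    """Top-ranked sources concatenated into one wide matrix."""

    matrix: np.ndarray  # (n_obs, 414 * top)
    provenance: list[tuple[int, int]]  # per column: (source_id, within-source index)
    selected_sources: list[int]  # rank order


def vector_losses(
    feature_sets,
    labels,
    folds: int = 10,
    seed: int = 0,
    classifiers: tuple[str, ...] = ("kNN", "SVM"),
) -> LossTable:
    """Score every per-source feature matrix by CV misclassification.

    ``feature_sets`` is a sequence of (n_obs, n_features) matrices, one
    per source (already normalised). Both classifier families are
    evaluated; the family with the lower mean loss across sources is
    recorded as ``chosen_classifier`` (greedy model selection).
    """
    y = np.asarray(labels)
    losses = np.empty((len(feature_sets), len(classifiers)))
    for i, X in enumerate(feature_sets):
        for j, family in enumerate(classifiers):
            pred = crossval_predict(X, y, ClassifierSpec(family), folds=folds, seed=seed)
            losses[i, j] = float(np.mean(pred != y))
    chosen = classifiers[int(np.argmin(losses.mean(axis=0)))]
    return LossTable(losses, chosen)


def select_and_merge(feature_sets, loss_table: LossTable, top: int = 20) -> MergedFeatures:
    """Concatenate the ``top`` lowest-loss sources in rank order.

    Ties in loss are broken toward the smaller source id.
    """
    if top < 1:
        raise ValueError("top must be >= 1")
    n = len(feature_sets)
    if top > n:
        raise ValueError(f"top={top} exceeds the {n} available sources")
    loss = loss_table.chosen_losses
    order = np.lexsort((np.arange(n), loss))  # loss ascending, then source id
    selected = [int(s) for s in order[:top]]
    matrix = np.hstack([feature_sets[s] for s in selected])
    provenance = [
        (s, j) for s in selected for j in range(feature_sets[s].shape[1])
    ]
    return MergedFeatures(matrix, provenance, selected)
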