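"""Per-source vectors, normalisation, loss ranking and top-k merging."""

import numpy as np
import pytest

from grasptex import (
    extract_all_feature_vectors,
    minmax_normalize,
    select_and_merge,
    synth_dataset,
    vector_losses,
)
from grasptex.selection import N_SOURCES, VECTOR_LEN, LossTable


@pytest.fixture(scope="module")
def study_record():
    """One DB1-shaped trial: two 3000-sample channels."""
    return synth_dataset(n_per_class=1, duration_s=6.0, seed=21).records[0]


def _toy_sources(n_sources=5, n_obs=60, n_feat=8, seed=0, separable=True):
    """Small per-source matrices with 6 balanced classes."""
    gen = np.random.default_rng(seed)
    labels = np.repeat([c for c in "CHLPST"], n_obs // 6)
    sets = []
    for _ in range(n_sources):
        X = gen.standard_normal((n_obs, n_feat)) * 0.01
        if separable:
            for i, lab in enumerate(labels):
                X[i, "CHLPST".index(lab) % n_feat] += 10.0  # one-hot style separation
        sets.append(X)
    return sets, labels


class TestExtractAllFeatureVectors:
    def test_study_shape(self, study_record):
        fv = extract_all_feature_vectors(study_record)
        assert fv.shape == (N_SOURCES, VECTOR_LEN) == (154, 414)
        assert np.all(np.isfinite(fv))
        # texture half is nonnegative counts
        assert fv[:, :384].min() >= 0

    def test_deterministic(self, study_record):
        a = extract_all_feature_vectors(study_record)
        b = extract_all_feature_vectors(study_record)
        np.testing.assert_array_equal(a, b)

    def test_scaling_moves_stats_not_texture(self, study_record):
        from grasptex.data import SignalRecord

        scaled = SignalRecord(
            2.0 * study_record.ch1, 2.0 * study_record.ch2, study_record.fs, study_record.label
        )
        a = extract_all_feature_vectors(study_record)
        b = extract_all_feature_vectors(scaled)
        np.testing.assert_array_equal(a[:, :384], b[:, :384])
        assert not np.allclose(a[:, 384:], b[:, 384:])


class TestMinmaxNormalize:
    def test_column_example(self):
        out = minmax_normalize(np.array([[2.0], [4.0], [6.0]]))
        np.testing.assert_allclose(out.ravel(), [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero(self):
        out = minmax_normalize(np.array([[5.0, 1.0], [5.0, 2.0]]))
        np.testing.assert_allclose(out[:, 0], 0.0)

    def test_range_is_unit(self, rng):
        X = rng.standard_normal((20, 6)) * 10
        out = minmax_normalize(X)
        np.testing.assert_allclose(out.min(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.max(axis=0), 1.0, atol=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            minmax_normalize(np.ones((1, 4)))


class TestVectorLosses:
    def test_separable_sources_have_zero_loss(self):
        sets, labels = _toy_sources()
        table = vector_losses(sets, labels, folds=5, seed=0)
        np.testing.assert_allclose(table.losses, 0.0)
        assert table.chosen_classifier in ("kNN", "SVM")

    def test_permuted_labels_chance_level(self):
        sets, labels = _toy_sources(n_sources=2, n_obs=120)
        perm = np.random.default_rng(5).permutation(len(labels))
        table = vector_losses(sets, np.asarray(labels)[perm], folds=5, seed=0)
        np.testing.assert_allclose(table.losses, 5 / 6, atol=0.1)

    def test_losses_in_unit_interval(self, rng):
        sets = [rng.standard_normal((60, 4)) for _ in range(3)]
        labels = np.repeat([c for c in "CHLPST"], 10)
        table = vector_losses(sets, labels, folds=5, seed=1)
        assert np.all((table.losses >= 0) & (table.losses <= 1))

    def test_deterministic_given_seed(self, rng):
        sets = [rng.standard_normal((60, 4)) for _ in range(2)]
        labels = np.repeat([c for c in "CHLPST"], 10)
        t1 = vector_losses(sets, labels, folds=5, seed=3)
        t2 = vector_losses(sets, labels, folds=5, seed=3)
        np.testing.assert_array_equal(t1.losses, t2.losses)

    def test_too_few_members_error(self):
        sets, labels = _toy_sources(n_obs=12)  # 2 per class < 5 folds
        with pytest.raises(ValueError, match="folds"):
            vector_losses(sets, labels, folds=5)


class TestSelectAndMerge:
    def test_width_and_provenance(self):
        sets, labels = _toy_sources(n_sources=6, n_feat=414)
        losses = np.tile(np.arange(6, dtype=float)[:, None] / 10, (1, 2))
        table = LossTable(losses, "kNN")
        merged = select_and_merge(sets, table, top=3)
        assert merged.matrix.shape[1] == 3 * 414
        assert merged.selected_sources == [0, 1, 2]
        # provenance is a bijection onto columns
        assert len(set(merged.provenance)) == merged.matrix.shape[1]
        src0, col0 = merged.provenance[0]
        np.testing.assert_array_equal(merged.matrix[:, 0], sets[src0][:, col0])

    def test_tie_breaks_to_smaller_source_id(self):
        sets, _ = _toy_sources(n_sources=4, n_feat=3)
        losses = np.array([[0.5, 0.5], [0.2, 0.2], [0.2, 0.2], [0.9, 0.9]])
        merged = select_and_merge(sets, LossTable(losses, "kNN"), top=2)
        assert merged.selected_sources == [1, 2]

    def test_rank_order_concatenation(self):
        sets, _ = _toy_sources(n_sources=3, n_feat=2)
        losses = np.array([[0.3, 0.3], [0.1, 0.1], [0.2, 0.2]])
        merged = select_and_merge(sets, LossTable(losses, "SVM"), top=3)
        assert merged.selected_sources == [1, 2, 0]

    def test_top_one_with_strict_best(self):
        sets, _ = _toy_sources(n_sources=3, n_feat=5)
        losses = np.array([[0.4, 0.4], [0.05, 0.05], [0.3, 0.3]])
        merged = select_and_merge(sets, LossTable(losses, "kNN"), top=1)
        assert merged.selected_sources == [1]
        assert merged.matrix.shape[1] == 5

    def test_invalid_top(self):
        sets, _ = _toy_sources(n_sources=3)
        losses = np.zeros((3, 2))
        with pytest.raises(ValueError):
            select_and_merge(sets, LossTable(losses, "kNN"), top=0)
        with pytest.raises(ValueError):
            select_and_merge(sets, LossTable(losses, "kNN"), top=4)
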