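"""Nearest-neighbour retrieval and strategy-probability tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import caselatent as cl
from caselatent.knn import (
    DEFAULT_K,
    DEFAULT_STRATEGY_THRESHOLD,
    LatentIndex,
    StrategyPrediction,
    build_index,
    distance_weights,
    find_neighbors,
    predict_strategies,
    strategies_by_case,
    strategy_probabilities,
)


def _random_index(n=120, dim=12, seed=0, metric="euclidean"):
    rng = np.random.default_rng(seed)
    return LatentIndex(
        case_ids=np.array([f"C{i:03d}" for i in range(n)], dtype=object),
        coordinates=rng.standard_normal((n, dim)),
        metric=metric,
    )


class TestFindNeighbors:
    def test_defaults_to_fifty_neighbours(self):
        index = _random_index(n=200)
        got = find_neighbors(index, np.zeros(12))
        assert got.k == DEFAULT_K == 50
        assert len(got.case_ids) == 50

    def test_indexed_query_is_its_own_nearest(self):
        index = _random_index()
        got = find_neighbors(index, index.coordinates[37], k=5)
        assert got.case_ids[0] == "C037"
        assert got.distances[0] == 0.0

    @pytest.mark.parametrize("metric", ["euclidean", "cosine"])
    def test_matches_brute_force(self, metric):
        index = _random_index(metric=metric, seed=4)
        rng = np.random.default_rng(5)
        for q in rng.standard_normal((20, 12)):
            got = find_neighbors(index, q, k=10)
            if metric == "euclidean":
                d = [float(np.linalg.norm(c - q)) for c in index.coordinates]
            else:
                qn = q / np.linalg.norm(q)
                d = [
                    1.0 - float(c @ qn / np.linalg.norm(c))
                    for c in index.coordinates
                ]
            expected = [cid for _, cid in sorted(zip(d, index.case_ids))[:10]]
            assert list(got.case_ids) == expected

    def test_result_invariant_to_index_permutation(self):
        index = _random_index(seed=8)
        rng = np.random.default_rng(9)
        perm = rng.permutation(len(index))
        shuffled = LatentIndex(case_ids=index.case_ids[perm], coordinates=index.coordinates[perm])
        q = rng.standard_normal(12)
        assert list(find_neighbors(index, q, k=15).case_ids) == list(
            find_neighbors(shuffled, q, k=15).case_ids
        )

    def test_bounds_and_empty_index(self):
        index = _random_index(n=10)
        with pytest.raises(ValueError):
            find_neighbors(index, np.zeros(12), k=11)
        with pytest.raises(ValueError):
            find_neighbors(index, np.zeros(12), k=0)
        empty = LatentIndex(case_ids=np.array([], dtype=object), coordinates=np.zeros((0, 12)))
        with pytest.raises(ValueError):
            find_neighbors(empty, np.zeros(12), k=1)


class TestDistanceWeights:
    @pytest.mark.parametrize(
        "distances,expected",
        [([1.0, 1.0], [0.5, 0.5]), ([1.0, 3.0], [0.75, 0.25]), ([0.0, 5.0], [1.0, 0.0])],
    )
    def test_hand_computed(self, distances, expected):
        assert np.allclose(distance_weights(np.array(distances)), expected)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            distance_weights(np.array([1.0, -0.5]))

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.0, 1e6), min_size=1, max_size=30))
    def test_weights_normalized_and_scale_invariant(self, d):
        d = np.asarray(d)
        w = distance_weights(d)
        assert abs(w.sum() - 1.0) < 1e-9
        assert (w >= 0).all()
        assert np.allclose(distance_weights(2.5 * d), w)


class TestStrategyProbabilities:
    def _neighbors(self, ids, distances):
        d = np.asarray(distances, dtype=float)
        return cl.knn.NeighborSet(
            query=np.zeros(2),
            case_ids=np.asarray(ids, dtype=object),
            distances=d,
            weights=distance_weights(d),
            k=len(ids),
        )

    def test_hand_computed_two_neighbours(self):
        nb = self._neighbors(["a", "b"], [1.0, 3.0])  # weights 0.75 / 0.25
        table = {"a": {"legal": 40.0, "RTW": 10.0}, "b": {"RTW": 20.0}}
        preds = {p.strategy: p for p in strategy_probabilities(nb, table)}
        assert preds["legal"].probability == pytest.approx(0.75)
        assert preds["legal"].expected_day == pytest.approx(40.0)
        assert preds["RTW"].probability == pytest.approx(1.0)
        assert preds["RTW"].expected_day == pytest.approx(0.75 * 10 + 0.25 * 20)

    def test_strategy_in_every_neighbour_is_certain(self):
        nb = self._neighbors(["a", "b", "c"], [1.0, 2.0, 3.0])
        table = {k: {"RTW": 5.0} for k in "abc"}
        preds = strategy_probabilities(nb, table)
        assert preds[0].probability == pytest.approx(1.0)

    def test_missing_neighbour_warns_and_counts_nothing(self):
        nb = self._neighbors(["a", "zzz"], [1.0, 1.0])
        with pytest.warns(UserWarning, match="zzz"):
            preds = strategy_probabilities(nb, {"a": {"RTW": 3.0}})
        assert preds[0].probability == pytest.approx(0.5)

    def test_sorted_by_probability_descending(self):
        nb = self._neighbors(["a", "b", "c"], [1.0, 1.0, 1.0])
        table = {"a": {"X": 1.0, "Y": 2.0}, "b": {"Y": 4.0}, "c": {"Y": 6.0, "Z": 1.0}}
        names = [p.strategy for p in strategy_probabilities(nb, table)]
        assert names == ["Y", "X", "Z"]


class TestPredictStrategies:
    def test_default_threshold(self):
        assert DEFAULT_STRATEGY_THRESHOLD == 0.40

    def test_zero_threshold_keeps_all_positive(self):
        preds = [StrategyPrediction("A", 0.01, 1.0), StrategyPrediction("B", 0.0, 1.0)]
        assert [p.strategy for p in predict_strategies(preds, 0.0)] == ["A"]

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            predict_strategies([], threshold=1.5)


def test_strategies_by_case_keeps_first_occurrence():
    logs = pd.DataFrame(
        {
            "case_id": ["c1", "c1", "c1"],
            "day_offset": [9, 4, 2],
            "field": ["strategy", "strategy", "estimated_SL"],
            "value": ["RTW", "RTW", "30"],
        }
    )
    assert strategies_by_case(logs) == {"c1": {"RTW": 4.0}}


def test_index_built_from_endpoints(tiny_trained):
    """Entry coordinates match an independent re-encoding at RTW day."""
    from caselatent.predictors import project_frame

    index = tiny_trained.index
    assert len(index) == len(tiny_trained.train)
    sample = tiny_trained.train.head(10)
    sl = pd.to_numeric(sample["sl_total_days"]).to_numpy(dtype=float)
    hd = pd.to_numeric(sample["days_until_hlm"], errors="coerce").to_numpy(dtype=float)
    z = project_frame(tiny_trained.vae, tiny_trained.codec, sample, sl, hd)
    assert np.allclose(index.coordinates[:10], z)


def test_open_cases_skipped_with_warning(tiny_trained):
    records = tiny_trained.train.head(20).copy()
    records.loc[records.index[:3], "sl_total_days"] = np.nan
    with pytest.warns(UserWarning, match="3 open cases"):
        index = build_index(tiny_trained.vae, tiny_trained.codec, records)
    assert len(index) == 17


def test_deterministic_class_strategies_recovered_for_benign_cases():
    """With strategies an exact function of the class and well-separated
    clusters, distance-weighted KNN recovers benign strategy sets almost
    perfectly as the index grows."""
    rng = np.random.default_rng(14)
    n = 2000
    labels = rng.random(n) < 0.2
    centres = np.where(labels[:, None], 6.0, -6.0)
    coords = centres + rng.standard_normal((n, 8))
    ids = np.array([f"C{i}" for i in range(n)], dtype=object)
    index = LatentIndex(case_ids=ids, coordinates=coords)
    table = {
        str(cid): ({"Legal": 50.0, "RTW": 80.0} if lab else {"RTW": 10.0})
        for cid, lab in zip(ids, labels)
    }
    correct = 0
    queries = rng.standard_normal((100, 8)) - 6.0  # benign side
    for q in queries:
        nb = find_neighbors(index, q, k=50)
        kept = {p.strategy for p in predict_strategies(strategy_probabilities(nb, table), 0.40)}
        correct += kept == {"RTW"}
    assert correct / 100 >= 0.99
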