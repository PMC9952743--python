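"""Distance-weighted nearest-neighbour strategy recommendation.

Closed historical cases are indexed by their endpoint latents
Z_End = E({C_s, RTW_Days}).  For a query point (typically a predicted
endpoint Z_p) the K = 50 nearest cases are retrieved by exact exhaustive
search, inverse-distance weights are computed, and each strategy's
probability is the total weight of the neighbours whose ground truth
contains it, with the expected occurrence day (offset from the date of
accident) the weight-averaged day among those neighbours.  Strategies
whose probability is strictly greater than the 40% threshold are
recommended.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_K = 50
DEFAULT_STRATEGY_THRESHOLD = 0.40


@dataclass(frozen=True)
class LatentIndex:
    case_ids: np.ndarray  # (n,) str
    coordinates: np.ndarray  # (n, latent_dim)
    metric: str = "euclidean"

    def __post_init__(self):
        if len(self.case_ids) != len(self.coordinates):
            raise ValueError("index: one coordinate row per case required")
        if self.metric not in ("euclidean", "cosine"):
            raise ValueError(f"unknown metric {self.metric!r}")

    def __len__(self) -> int:
        return len(self.case_ids)

    def save(self, path) -> None:
        np.savez(path, case_ids=self.case_ids.astype(str), coordinates=self.coordinates)
        manifest = {"metric": self.metric, "k_default": DEFAULT_K, "n_entries": len(self)}
        with open(str(path) + ".json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, path) -> "LatentIndex":
        data = np.load(path, allow_pickle=False)
        with open(str(path) + ".json") as fh:
            manifest = json.load(fh)
        return cls(case_ids=data["case_ids"], coordinates=data["coordinates"], metric=manifest["metric"])


@dataclass(frozen=True)
class NeighborSet:
    query: np.ndarray
    case_ids: np.ndarray
    distances: np.ndarray  # non-decreasing
    weights: np.ndarray  # sum to 1
    k: int


@dataclass(frozen=True)
class StrategyPrediction:
    strategy: str
    probability: float
    expected_day: float | None

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "probability": self.probability,
            "expected_day": self.expected_day,
        }


def build_index(vae, codec, closed_records: pd.DataFrame, metric: str = "euclidean") -> LatentIndex:
    """Embed closed cases at their true RTW day; open cases are skipped."""
    from .predictors import endpoint_latents

    sl = pd.to_numeric(closed_records["sl_total_days"], errors="coerce")
    open_mask = sl.isna()
    if open_mask.any():
        warnings.warn(f"skipping {int(open_mask.sum())} open cases without RTW_Days", stacklevel=2)
    usable = closed_records.loc[~open_mask.to_numpy()]
    z_end = endpoint_latents(vae, codec, usable)
    return LatentIndex(case_ids=usable["case_id"].to_numpy(dtype=object), coordinates=z_end, metric=metric)


def _distances(index: LatentIndex, query: np.ndarray) -> np.ndarray:
    q = np.asarray(query, dtype=float).ravel()
    if index.metric == "euclidean":
        return np.sqrt(np.sum((index.coordinates - q) ** 2, axis=1))
    qn = q / max(np.linalg.norm(q), 1e-12)
    cn = index.coordinates / np.maximum(np.linalg.norm(index.coordinates, axis=1, keepdims=True), 1e-12)
    return 1.0 - cn @ qn


def find_neighbors(index: LatentIndex, query: np.ndarray, k: int = DEFAULT_K) -> NeighborSet:
    """Exact K-nearest search; ties at equal distance break on case_id."""
    if len(index) == 0:
        raise ValueError("index is empty")
    if not (1 <= k <= len(index)):
        raise ValueError(f"k={k} must lie in [1, {len(index)}]")
    d = _distances(index, query)
    order = np.lexsort((index.case_ids.astype(str), d))[:k]
    dk = d[order]
    return NeighborSet(
        query=np.asarray(query, dtype=float).ravel(),
        case_ids=index.case_ids[order],
        distances=dk,
        weights=distance_weights(dk),
        k=k,
    )


def distance_weights(distances: np.ndarray) -> np.ndarray:
    """Normalized inverse-distance weights.

    Exact matches (distance 0) take all the mass, shared equally among
    themselves; otherwise w_i = (1/d_i) / sum_j (1/d_j).
    """
    d = np.asarray(distances, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    if len(d) == 0:
        return np.array([])
    zero = d == 0.0
    if zero.any():
        w = np.zeros_like(d)
        w[zero] = 1.0 / zero.sum()
        return w
    # scale by the smallest distance before inverting so that very small
    # (even subnormal) distances cannot overflow 1/d
    inv = d.min() / d
    return inv / inv.sum()


def strategies_by_case(logs: pd.DataFrame) -> dict[str, dict[str, float]]:
    """case_id -> {strategy: first occurrence day} from dynamic logs."""
    strat = logs.loc[logs["field"] == "strategy"]
    table: dict[str, dict[str, float]] = {}
    for cid, day, name in zip(strat["case_id"], strat["day_offset"], strat["value"]):
        entry = table.setdefault(str(cid), {})
        day = float(day)
        if name not in entry or day < entry[name]:
            entry[name] = day
    return table


def strategy_probabilities(
    neighbors: NeighborSet,
    case_strategies: dict[str, dict[str, float]],
    aggregate: str = "mean",
) -> list[StrategyPrediction]:
    """Distance-weighted strategy probabilities and expected days.

    P(s) is the total weight of neighbours whose ground truth contains s
    (probabilities are not normalized across strategies — a case can have
    several).  The expected day is the weight-renormalized average (or
    median) of s's occurrence days among those neighbours.
    """
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate: must be 'mean' or 'median'")
    probs: dict[str, float] = {}
    day_obs: dict[str, list[tuple[float, float]]] = {}
    for cid, w in zip(neighbors.case_ids, neighbors.weights):
        entry = case_strategies.get(str(cid))
        if entry is None:
            warnings.warn(f"neighbour {cid} missing from dynamic logs; treated as no strategies", stacklevel=2)
            continue
        for name, day in entry.items():
            probs[name] = probs.get(name, 0.0) + float(w)
            day_obs.setdefault(name, []).append((float(w), float(day)))
    out = []
    for name in sorted(probs, key=lambda s: (-probs[s], s)):
        obs = day_obs[name]
        wsum = sum(w for w, _ in obs)
        if wsum > 0:
            if aggregate == "mean":
                day = sum(w * d for w, d in obs) / wsum
            else:
                order = sorted(obs, key=lambda x: x[1])
                cum, day = 0.0, order[-1][1]
                for w, d in order:
                    cum += w
                    if cum >= wsum / 2:
                        day = d
                        break
        else:  # all mass on exact matches elsewhere; fall back to plain mean
            day = float(np.mean([d for _, d in obs]))
        out.append(StrategyPrediction(strategy=name, probability=min(1.0, probs[name]), expected_day=day))
    return out


def predict_strategies(
    predictions: list[StrategyPrediction], threshold: float = DEFAULT_STRATEGY_THRESHOLD
) -> list[StrategyPrediction]:
    """Strategies whose probability is strictly greater than the threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold: must lie in [0, 1]")
    return [p for p in predictions if p.probability > threshold]
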