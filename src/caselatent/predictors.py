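"""Latent-path prediction: case endpoints, PD and the HLM cliff.

A case is modelled as a path through the latent space: it starts at
Z_0 = E({C_s, 0}) and, after t days, sits at Z_t = E({C_s, t}).  Four maps
operate on these points:

* benign endpoint  Z_p = p_blm(Z_0) — benign cases follow a common pattern
  that is derivable from the information available at the start, so only
  Z_0 is used, whatever the query day;
* serious endpoint Z_p = p_hlm_endpoint(Z_t) with t the HLM day;
* PD estimator     pd = p_pd(Z_p);
* HLM classifier   L_HLM = p_hlm_classifier(Z_t) in [0, 1], trained on
  latent points sampled along each case's timeline, so the probability of
  needing high-level management grows as a case outlives its common
  timeframe — sweeping it over a day grid traces the HLM cliff.

Predicted sick-leave duration (RTW_Days) is read off the decoded
sick-leave field of D(Z_p).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.neural_network import MLPClassifier, MLPRegressor

from .cohort import BLM, HLM
from .preprocess import FeatureCodec
from .vae import MixedVAE

MIN_REGIME_CASES = 10


class RegimeUnavailableError(RuntimeError):
    """A predictor regime had too few training cases to be fitted."""


class PredictorConfig(BaseModel):
    family: str = Field(default="mlp", pattern="^(mlp|linear)$")
    hidden: tuple[int, int] = (64, 64)
    max_iter: int = 500
    #: probability above which the classifier declares a case serious
    hlm_threshold: float = Field(default=0.5, ge=0.0, le=1.0)
    #: latent points sampled per case when training the classifier
    classifier_t_samples: int = Field(default=4, ge=1)
    seed: int = 0

    model_config = ConfigDict(frozen=True)


@dataclass(frozen=True)
class LatentPoint:
    coordinates: np.ndarray
    t: float
    case_id: str | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("latent coordinates must be finite")


@dataclass(frozen=True)
class CaseOutcome:
    rtw_days: float
    pd_percent: float
    hlm_probability: float
    regime_used: str

    def to_dict(self) -> dict:
        return {
            "rtw_days": self.rtw_days,
            "pd_percent": self.pd_percent,
            "hlm_probability": self.hlm_probability,
            "regime_used": self.regime_used,
        }


@dataclass(frozen=True)
class CliffEstimate:
    case_id: str | None
    day_grid: np.ndarray
    hlm_probability: np.ndarray
    threshold: float
    crossing_day: float | None


def _regressor(cfg: PredictorConfig, seed_offset: int):
    if cfg.family == "linear":
        return Ridge(alpha=1.0)
    return MLPRegressor(
        hidden_layer_sizes=cfg.hidden,
        max_iter=cfg.max_iter,
        random_state=cfg.seed + seed_offset,
        early_stopping=False,
    )


def _classifier(cfg: PredictorConfig, seed_offset: int):
    if cfg.family == "linear":
        return LogisticRegression(max_iter=1000)
    return MLPClassifier(
        hidden_layer_sizes=cfg.hidden,
        max_iter=cfg.max_iter,
        random_state=cfg.seed + seed_offset,
    )


def project_frame(
    vae: MixedVAE,
    codec: FeatureCodec,
    records: pd.DataFrame,
    t: np.ndarray,
    hlm_day: np.ndarray | None = None,
) -> np.ndarray:
    """Z_t = E({C_s, t}) for a frame of cases at per-case days."""
    batch = codec.encode_frame(records, np.asarray(t, dtype=float), hlm_day)
    return vae.encode(batch.x_cont, batch.x_cat)


def project_case(
    vae: MixedVAE,
    codec: FeatureCodec,
    record: pd.Series | dict,
    t: float,
    hlm_day: float | None = None,
) -> LatentPoint:
    """One case at day ``t``; ``t=0`` gives the path start Z_0."""
    if t < 0:
        raise ValueError("t: must be non-negative")
    frame = pd.DataFrame([record])
    hd = None if hlm_day is None else np.array([float(hlm_day)])
    z = project_frame(vae, codec, frame, np.array([float(t)]), hd)
    cid = record.get("case_id") if isinstance(record, (dict, pd.Series)) else None
    return LatentPoint(coordinates=z[0], t=float(t), case_id=cid)


def endpoint_latents(vae: MixedVAE, codec: FeatureCodec, records: pd.DataFrame) -> np.ndarray:
    """Z_End = E({C_s, RTW_Days}) for closed cases (HLM day known)."""
    sl = pd.to_numeric(records["sl_total_days"]).to_numpy(dtype=float)
    hlm_day = pd.to_numeric(records["days_until_hlm"], errors="coerce").to_numpy(dtype=float)
    return project_frame(vae, codec, records, sl, hlm_day)


class PredictorSet:
    """The fitted endpoint/PD/classifier maps for one trained VAE."""

    def __init__(self, config: PredictorConfig, latent_dim: int):
        self.config = config
        self.latent_dim = latent_dim
        self.p_blm = None
        self.p_hlm_endpoint = None
        self.p_pd = None
        self.p_hlm_classifier = None
        self.unavailable: dict[str, str] = {}

    # regime predictors -------------------------------------------------
    def predict_endpoint(self, z: np.ndarray, regime: str) -> np.ndarray:
        mdl = self.p_blm if regime == BLM else self.p_hlm_endpoint
        if mdl is None:
            raise RegimeUnavailableError(
                f"{regime} endpoint predictor unavailable: {self.unavailable.get(regime, 'not fitted')}"
            )
        return np.atleast_2d(mdl.predict(np.atleast_2d(z)))

    def predict_pd(self, z_p: np.ndarray) -> np.ndarray:
        return np.maximum(0.0, np.atleast_1d(self.p_pd.predict(np.atleast_2d(z_p))))

    def hlm_probability(self, z_t: np.ndarray) -> np.ndarray:
        proba = self.p_hlm_classifier.predict_proba(np.atleast_2d(z_t))
        hlm_col = list(self.p_hlm_classifier.classes_).index(1)
        return proba[:, hlm_col]


def train_predictors(
    vae: MixedVAE,
    codec: FeatureCodec,
    train_records: pd.DataFrame,
    config: PredictorConfig | None = None,
) -> PredictorSet:
    """Fit the predictor set on closed training cases.

    The benign endpoint map is fitted from Z_0 only; the serious endpoint
    map from Z_t at each case's HLM day; the PD estimator on true-endpoint
    latents; and the classifier on latent points sampled uniformly along
    each case's timeline with the case's class as label (HLM day withheld,
    as it would be for an open case being triaged).
    """
    config = config or PredictorConfig()
    pset = PredictorSet(config, vae.config.latent_dim)
    rng = np.random.default_rng(config.seed)

    labels = train_records["blm_hlm_flag"].to_numpy()
    sl = pd.to_numeric(train_records["sl_total_days"]).to_numpy(dtype=float)
    z_end = endpoint_latents(vae, codec, train_records)

    blm_mask = labels == BLM
    hlm_mask = labels == HLM

    if blm_mask.sum() >= MIN_REGIME_CASES:
        blm = train_records.loc[blm_mask]
        z0 = project_frame(vae, codec, blm, np.zeros(len(blm)))
        pset.p_blm = _regressor(config, 1).fit(z0, z_end[blm_mask])
    else:
        pset.unavailable[BLM] = f"only {int(blm_mask.sum())} benign cases (< {MIN_REGIME_CASES})"

    if hlm_mask.sum() >= MIN_REGIME_CASES:
        hlm = train_records.loc[hlm_mask]
        hd = pd.to_numeric(hlm["days_until_hlm"]).to_numpy(dtype=float)
        z_hlm = project_frame(vae, codec, hlm, hd, hd)
        pset.p_hlm_endpoint = _regressor(config, 2).fit(z_hlm, z_end[hlm_mask])
    else:
        pset.unavailable[HLM] = f"only {int(hlm_mask.sum())} serious cases (< {MIN_REGIME_CASES})"

    pd_true = pd.to_numeric(train_records["form7_pd"]).to_numpy(dtype=float)
    pset.p_pd = _regressor(config, 3).fit(z_end, pd_true)

    # classifier: m latent snapshots per case at t ~ U[0, SL]
    m = config.classifier_t_samples
    reps = train_records.loc[train_records.index.repeat(m)].reset_index(drop=True)
    t_samples = rng.uniform(0.0, np.repeat(sl, m))
    z_t = project_frame(vae, codec, reps, t_samples)
    y = (reps["blm_hlm_flag"] == HLM).to_numpy().astype(int)
    if len(np.unique(y)) < 2:
        pset.unavailable["classifier"] = "single-class cohort; HLM probability fixed at class rate"
        pset.p_hlm_classifier = _ConstantClassifier(float(y.mean()))
    else:
        pset.p_hlm_classifier = _classifier(config, 4).fit(z_t, y)
    return pset


class _ConstantClassifier:
    """Degenerate stand-in when the cohort contains a single class."""

    def __init__(self, rate: float):
        self.rate = rate
        self.classes_ = [0, 1]

    def predict_proba(self, X):
        X = np.atleast_2d(X)
        return np.column_stack([np.full(len(X), 1 - self.rate), np.full(len(X), self.rate)])


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def decode_endpoint(vae: MixedVAE, codec: FeatureCodec, z_p: np.ndarray) -> pd.DataFrame:
    y_cont, probs = vae.decode(np.atleast_2d(z_p))
    decoded = codec.decode_outputs(y_cont, probs)
    decoded["rtw_days"] = np.maximum(0.0, _round_half_up(decoded["sl_total_days"]))
    return decoded


def predict_outcome(
    pset: PredictorSet,
    vae: MixedVAE,
    codec: FeatureCodec,
    record: pd.Series | dict,
    t: float = 0.0,
    hlm_day: float | None = None,
    force_regime: str | None = None,
) -> CaseOutcome:
    """Predict where one case ends.

    The regime is the classifier's call at day ``t`` unless forced.  For
    serious cases without a known HLM day the current day stands in for
    it — the classifier has just fired, so today is the HLM day as far as
    the model knows.
    """
    z_t = project_case(vae, codec, record, t).coordinates
    prob = float(pset.hlm_probability(z_t)[0])
    regime = force_regime or (HLM if prob > pset.config.hlm_threshold else BLM)
    if regime == BLM:
        z_query = project_case(vae, codec, record, 0.0).coordinates
    else:
        hd = float(hlm_day) if hlm_day is not None else float(t)
        z_query = project_case(vae, codec, record, hd, hlm_day=hd).coordinates
    z_p = pset.predict_endpoint(z_query, regime)
    decoded = decode_endpoint(vae, codec, z_p)
    return CaseOutcome(
        rtw_days=float(decoded["rtw_days"].iloc[0]),
        pd_percent=float(pset.predict_pd(z_p)[0]),
        hlm_probability=prob,
        regime_used=regime,
    )


def predict_outcomes_frame(
    pset: PredictorSet,
    vae: MixedVAE,
    codec: FeatureCodec,
    records: pd.DataFrame,
    regime: str,
    hlm_day: np.ndarray | None = None,
) -> pd.DataFrame:
    """Vectorized endpoint prediction for a frame, forced to one regime.

    Mirrors the evaluation protocol: benign cases are predicted from the
    path start, serious cases from the day HLM was applied.
    """
    if regime == BLM:
        z_query = project_frame(vae, codec, records, np.zeros(len(records)))
    else:
        hd = (
            np.asarray(hlm_day, dtype=float)
            if hlm_day is not None
            else pd.to_numeric(records["days_until_hlm"], errors="coerce").to_numpy(dtype=float)
        )
        z_query = project_frame(vae, codec, records, hd, hd)
    z_p = pset.predict_endpoint(z_query, regime)
    decoded = decode_endpoint(vae, codec, z_p)
    out = pd.DataFrame(
        {
            "case_id": records["case_id"].to_numpy(),
            "rtw_days": decoded["rtw_days"].to_numpy(),
            "pd_percent": pset.predict_pd(z_p),
            "regime_used": regime,
        }
    )
    out["z_p"] = list(np.atleast_2d(z_p))
    return out


def hlm_cliff(
    pset: PredictorSet,
    vae: MixedVAE,
    codec: FeatureCodec,
    record: pd.Series | dict,
    day_grid: np.ndarray,
    threshold: float | None = None,
) -> CliffEstimate:
    """HLM probability along a day grid and its first threshold crossing."""
    day_grid = np.asarray(day_grid, dtype=float)
    if len(day_grid) == 0 or np.any(np.diff(day_grid) <= 0):
        raise ValueError("day_grid: must be nonempty and strictly increasing")
    threshold = pset.config.hlm_threshold if threshold is None else float(threshold)
    frame = pd.DataFrame([record] * len(day_grid))
    z = project_frame(vae, codec, frame, day_grid)
    probs = pset.hlm_probability(z)
    above = np.nonzero(probs > threshold)[0]
    crossing = float(day_grid[above[0]]) if len(above) else None
    cid = record.get("case_id") if isinstance(record, (dict, pd.Series)) else None
    return CliffEstimate(
        case_id=cid, day_grid=day_grid, hlm_probability=probs, threshold=threshold, crossing_day=crossing
    )
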