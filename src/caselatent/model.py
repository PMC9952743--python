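"""High-level modelling interface.

``WorkInjuryModel`` is built from a frame of closed static case records
(plus, optionally, the dynamic change logs and the generating ground truth
when evaluating on synthetic cohorts).  ``fit`` runs the whole estimation
pipeline — cleaning, train/test split, scaler/vocabulary fitting, VAE
training, latent-path predictor fitting and endpoint indexing — and
returns a ``WorkInjuryResults`` with prediction, recommendation,
evaluation and summary services.

    model = WorkInjuryModel.from_cohort(cohort)
    results = model.fit(seed=0)
    print(results.summary())
    outcome = results.predict_outcome(record, t=30)
    plan = results.recommend(record)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import knn as knn_mod
from . import predictors as pred_mod
from .cohort import BLM, HLM, Cohort
from .preprocess import (
    FeatureCodec,
    drop_incomplete,
    fit_codec,
    load_logs,
    load_static,
    split_train_test,
)
from .vae import FeatureWidths, MixedVAE, VaeConfig


def _truth_sets(truth: pd.DataFrame) -> tuple[dict[str, set[str]], dict[str, str]]:
    sets, labels = {}, {}
    for row in truth.itertuples(index=False):
        sets[row.case_id] = set(json.loads(row.strategies))
        labels[row.case_id] = row.class_label
    return sets, labels


class WorkInjuryModel:
    """Latent-space model of work-injury case trajectories."""

    def __init__(
        self,
        static: pd.DataFrame,
        logs: pd.DataFrame | None = None,
        truth: pd.DataFrame | None = None,
        vae_config: VaeConfig | None = None,
        predictor_config: pred_mod.PredictorConfig | None = None,
        split_ratio: float = 0.05,
        use_alertness: bool = True,
        knn_metric: str = "euclidean",
        k: int = knn_mod.DEFAULT_K,
        strategy_threshold: float = knn_mod.DEFAULT_STRATEGY_THRESHOLD,
        vae_t_samples: int = 4,
    ):
        self.static = static
        self.logs = logs
        self.truth = truth
        self.vae_config = vae_config or VaeConfig()
        self.predictor_config = predictor_config
        self.split_ratio = split_ratio
        self.use_alertness = use_alertness
        self.knn_metric = knn_metric
        self.k = k
        self.strategy_threshold = strategy_threshold
        self.vae_t_samples = max(2, int(vae_t_samples))

    @classmethod
    def from_cohort(cls, cohort: Cohort, **kwargs) -> "WorkInjuryModel":
        return cls(static=cohort.static, logs=cohort.logs, truth=cohort.truth, **kwargs)

    @classmethod
    def from_csv(cls, static_path, logs_path=None, **kwargs) -> "WorkInjuryModel":
        static, problems = load_static(static_path)
        if problems:
            valid_ids = _invalid_rows(static, problems)
            static = static.drop(index=valid_ids).reset_index(drop=True)
        logs = load_logs(logs_path) if logs_path else None
        return cls(static=static, logs=logs, **kwargs)

    # -- estimation -------------------------------------------------------
    def fit(self, seed: int = 0, epochs: int | None = None) -> "WorkInjuryResults":
        """Run the full pipeline; all randomness derives from ``seed``."""
        records, n_dropped = drop_incomplete(self.static)
        train, test = split_train_test(records, self.split_ratio, seed=seed + 2)
        codec = fit_codec(train, use_alertness=self.use_alertness)

        vae_cfg = self.vae_config.model_copy(update={"seed": seed})
        widths = FeatureWidths(
            n_cont_in=codec.n_cont_in,
            cat_in_width=codec.cat_in_width,
            n_cont_out=codec.n_cont_out,
            cat_out_groups=tuple(w for _, w in codec.cat_output_groups),
        )
        vae = MixedVAE(vae_cfg, widths)

        x_cont, x_cat, y_cont, y_cat = self._training_matrix(codec, train, seed=seed + 3)
        vae.train(x_cont, x_cat, y_cont, y_cat, epochs=epochs)

        pcfg = (self.predictor_config or pred_mod.PredictorConfig()).model_copy(update={"seed": seed + 1})
        pset = pred_mod.train_predictors(vae, codec, train, pcfg)
        index = knn_mod.build_index(vae, codec, train, metric=self.knn_metric)
        return WorkInjuryResults(
            model=self,
            codec=codec,
            vae=vae,
            predictors=pset,
            index=index,
            train=train,
            test=test,
            n_dropped=n_dropped,
            seed=seed,
        )

    def _training_matrix(self, codec: FeatureCodec, train: pd.DataFrame, seed: int):
        """Rows for VAE training: each case at t = 0, t = RTW and
        ``vae_t_samples - 2`` uniform days in between; the HLM day enters
        only once the timeline has reached it."""
        rng = np.random.default_rng(seed)
        m = self.vae_t_samples
        sl = pd.to_numeric(train["sl_total_days"]).to_numpy(dtype=float)
        hlm_day = pd.to_numeric(train["days_until_hlm"], errors="coerce").to_numpy(dtype=float)
        reps = train.loc[train.index.repeat(m)].reset_index(drop=True)
        t = np.empty(len(train) * m)
        t[0::m] = 0.0
        t[1::m] = sl
        for j in range(2, m):
            t[j::m] = rng.uniform(0.0, sl)
        hd = np.repeat(hlm_day, m)
        hd = np.where(np.isnan(hd) | (t < hd), np.nan, hd)
        batch = codec.encode_frame(reps, t, hd, with_targets=True)
        return batch.x_cont, batch.x_cat, batch.y_cont, batch.y_cat_idx


def _invalid_rows(static: pd.DataFrame, problems: list[str]) -> list[int]:
    rows = []
    for p in problems:
        if p.startswith("row "):
            rows.append(int(p.split()[1].rstrip(":")))
    return sorted(set(rows))


@dataclass
class EvaluationResult:
    error_table: pd.DataFrame
    strategy_reports: dict
    n_test: int
    n_dropped: int

    def to_json(self) -> str:
        payload = {
            "errors": json.loads(self.error_table.to_json(orient="index")),
            "strategy": {
                cls: {
                    "mean_per_case_accuracy": rep.mean_accuracy,
                    "per_strategy_recall": rep.per_strategy_recall,
                    "per_strategy_precision": rep.per_strategy_precision,
                    "n_cases": rep.n_cases,
                    "n_excluded_empty_truth": rep.n_excluded_empty_truth,
                }
                for cls, rep in self.strategy_reports.items()
            },
            "n_test": self.n_test,
            "n_dropped": self.n_dropped,
        }
        return json.dumps(payload, indent=1, sort_keys=True, ensure_ascii=False, default=float)


class WorkInjuryResults:
    """Fitted pipeline: trained VAE, predictor set and endpoint index."""

    def __init__(self, model, codec, vae, predictors, index, train, test, n_dropped, seed):
        self.model = model
        self.codec = codec
        self.vae = vae
        self.predictors = predictors
        self.index = index
        self.train = train
        self.test = test
        self.n_dropped = n_dropped
        self.seed = seed

    # -- prediction services ---------------------------------------------
    def project_case(self, record, t: float, hlm_day: float | None = None):
        return pred_mod.project_case(self.vae, self.codec, record, t, hlm_day)

    def predict_outcome(self, record, t: float = 0.0, hlm_day=None, force_regime=None):
        return pred_mod.predict_outcome(
            self.predictors, self.vae, self.codec, record, t, hlm_day, force_regime
        )

    def hlm_cliff(self, record, day_grid, threshold=None):
        return pred_mod.hlm_cliff(self.predictors, self.vae, self.codec, record, day_grid, threshold)

    def recommend(
        self,
        record,
        t: float = 0.0,
        hlm_day=None,
        force_regime=None,
        k: int | None = None,
        threshold: float | None = None,
    ) -> dict:
        """Predict the endpoint, retrieve similar closed cases and emit the
        strategies whose weighted probability clears the threshold."""
        if self.model.logs is None:
            raise ValueError("strategy recommendation needs dynamic logs")
        outcome = self.predict_outcome(record, t, hlm_day, force_regime)
        regime = outcome.regime_used
        if regime == BLM:
            z_q = self.project_case(record, 0.0).coordinates
        else:
            hd = float(hlm_day) if hlm_day is not None else float(t)
            z_q = self.project_case(record, hd, hlm_day=hd).coordinates
        z_p = self.predictors.predict_endpoint(z_q, regime)[0]
        neighbors = knn_mod.find_neighbors(self.index, z_p, k or self.model.k)
        table = knn_mod.strategies_by_case(self.model.logs)
        all_preds = knn_mod.strategy_probabilities(neighbors, table)
        thr = self.model.strategy_threshold if threshold is None else threshold
        return {
            "outcome": outcome,
            "neighbors": neighbors,
            "strategies": all_preds,
            "recommended": knn_mod.predict_strategies(all_preds, thr),
        }

    # -- evaluation -------------------------------------------------------
    def _forced_regime_predictions(self, records: pd.DataFrame) -> pd.DataFrame:
        """Mirror the comparison protocol: benign cases predicted from the
        start, serious cases from their HLM day."""
        parts = []
        for cls in (BLM, HLM):
            sub = records.loc[records["blm_hlm_flag"] == cls]
            if len(sub) == 0:
                continue
            parts.append(
                pred_mod.predict_outcomes_frame(self.predictors, self.vae, self.codec, sub, cls)
            )
        return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()

    def evaluate(self, records: pd.DataFrame | None = None, truth: pd.DataFrame | None = None) -> EvaluationResult:
        """Score the pipeline on held-out cases against ground truth."""
        records = self.test if records is None else records
        truth = self.model.truth if truth is None else truth
        if truth is None:
            raise ValueError("evaluation needs ground truth")
        truth = truth.loc[truth["case_id"].isin(records["case_id"])]
        preds = self._forced_regime_predictions(records)
        model_report = ev.sl_pd_errors(preds, truth, condition="model")
        if self.model.logs is not None:
            table = ev.human_comparison(model_report, self.model.logs, truth)
        else:
            table = ev.report_table([model_report])

        strategy_reports = {}
        if self.model.logs is not None and "strategies" in truth.columns:
            truth_sets, labels = _truth_sets(truth)
            log_table = knn_mod.strategies_by_case(self.model.logs)
            predicted: dict[str, set[str]] = {}
            for row in preds.itertuples(index=False):
                neighbors = knn_mod.find_neighbors(self.index, row.z_p, self.model.k)
                strat = knn_mod.strategy_probabilities(neighbors, log_table)
                selected = knn_mod.predict_strategies(strat, self.model.strategy_threshold)
                predicted[row.case_id] = {s.strategy for s in selected}
            strategy_reports = ev.strategy_accuracy(predicted, truth_sets, labels)
        return EvaluationResult(
            error_table=table,
            strategy_reports=strategy_reports,
            n_test=len(records),
            n_dropped=self.n_dropped,
        )

    # -- persistence ------------------------------------------------------
    def save(self, directory) -> None:
        """Write the fitted pipeline as a directory artefact."""
        import joblib
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.vae.save(directory / "vae.npz")
        (directory / "codec.json").write_text(self.codec.to_json())
        joblib.dump(self.predictors, directory / "predictors.joblib")
        self.index.save(directory / "index.npz")
        self.train.to_csv(directory / "train.csv", index=False)
        self.test.to_csv(directory / "test.csv", index=False)
        pd.DataFrame(self.vae.loss_trace).to_csv(directory / "loss_trace.csv", index=False)
        meta = {
            "seed": self.seed,
            "n_dropped": self.n_dropped,
            "split_ratio": self.model.split_ratio,
            "use_alertness": self.model.use_alertness,
            "k": self.model.k,
            "strategy_threshold": self.model.strategy_threshold,
            "knn_metric": self.model.knn_metric,
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory, logs: pd.DataFrame | None = None, truth: pd.DataFrame | None = None) -> "WorkInjuryResults":
        import joblib
        from pathlib import Path

        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        vae = MixedVAE.load(directory / "vae.npz")
        codec = FeatureCodec.from_json((directory / "codec.json").read_text())
        predictors = joblib.load(directory / "predictors.joblib")
        index = knn_mod.LatentIndex.load(directory / "index.npz")
        train = pd.read_csv(directory / "train.csv", dtype={"case_id": str})
        test = pd.read_csv(directory / "test.csv", dtype={"case_id": str})
        model = WorkInjuryModel(
            static=pd.concat([train, test], ignore_index=True),
            logs=logs,
            truth=truth,
            split_ratio=meta["split_ratio"],
            use_alertness=meta["use_alertness"],
            knn_metric=meta["knn_metric"],
            k=meta["k"],
            strategy_threshold=meta["strategy_threshold"],
        )
        return cls(
            model=model,
            codec=codec,
            vae=vae,
            predictors=predictors,
            index=index,
            train=train,
            test=test,
            n_dropped=meta["n_dropped"],
            seed=meta["seed"],
        )

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        w = self.vae.widths
        final = self.vae.loss_trace[-1] if self.vae.loss_trace else {}
        lines = [
            "Work-injury latent-path model",
            "=" * 64,
            f"cases: {len(self.train)} train / {len(self.test)} test"
            f" (dropped incomplete: {self.n_dropped})",
            f"latent dim: {self.vae.config.latent_dim}; processing: "
            f"{self.vae.config.processing_layers} x {self.vae.config.processing_width}",
            f"encoder widths: {w.n_cont_in} continuous, {w.cat_in_width} one-hot",
            f"decoder widths: {w.n_cont_out} continuous, groups {list(w.cat_out_groups)}",
            f"parameters: {self.vae.parameter_count():,}",
            f"kl_weight: {self.vae.config.kl_weight}; epochs run: {len(self.vae.loss_trace)}",
        ]
        if final:
            lines.append(
                "final loss: total {total:.4f} (cont {continuous:.4f}, "
                "cat {categorical:.4f}, kl {kl:.4f})".format(**final)
            )
        if self.predictors.unavailable:
            lines.append(f"unavailable regimes: {self.predictors.unavailable}")
        lines.append(
            f"endpoint index: {len(self.index)} cases, metric {self.index.metric}, "
            f"k={self.model.k}, strategy threshold {self.model.strategy_threshold}"
        )
        return "\n".join(lines)


def alertness_ablation(
    static: pd.DataFrame,
    logs: pd.DataFrame,
    truth: pd.DataFrame,
    seed: int = 0,
    epochs: int | None = None,
    **model_kwargs,
) -> dict:
    """Two full train+evaluate runs differing only in the alertness feature.

    Returns the paired results and reports under 'with_alertness' /
    'without_alertness'; the same seed bundle is used for both runs so the
    difference is attributable to the feature alone.
    """
    out = {}
    for tag, use in (("with_alertness", True), ("without_alertness", False)):
        model = WorkInjuryModel(
            static=static, logs=logs, truth=truth, use_alertness=use, **model_kwargs
        )
        results = model.fit(seed=seed, epochs=epochs)
        out[tag] = {
            "results": results,
            "evaluation": results.evaluate(),
            "n_cont_in": results.vae.widths.n_cont_in,
        }
    return out
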