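"""Desk-scale evaluation: prediction errors, ablation, human comparison
and strategy accuracy.

All error metrics are mean absolute errors reported separately for benign
(BLM) and serious (HLM) cases, mirroring the standard results layout
(rows = condition, columns = SL/PD x BLM/HLM).  The human baseline follows
the case-manager comparison protocol: for a benign case the first estimate
ever made is used; for a serious case, the estimate nearest in time to the
day high-level management was applied.

Strategy accuracy applies the >40% rule upstream; per-case accuracy is
|predicted ∩ truth| / |truth| (false positives are not penalized by this
metric, so a precision column is reported alongside); per-strategy
accuracy is recall over the cases whose ground truth contains the
strategy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import BLM, HLM


@dataclass(frozen=True)
class ErrorReport:
    condition: str
    sl_mae_blm: float | None
    sl_mae_hlm: float | None
    pd_mae_blm: float | None
    pd_mae_hlm: float | None
    n_blm: int
    n_hlm: int

    def to_row(self) -> dict:
        return {
            "condition": self.condition,
            "sl_mae_blm": self.sl_mae_blm,
            "sl_mae_hlm": self.sl_mae_hlm,
            "pd_mae_blm": self.pd_mae_blm,
            "pd_mae_hlm": self.pd_mae_hlm,
            "n_blm": self.n_blm,
            "n_hlm": self.n_hlm,
        }


def _mae(a: np.ndarray, b: np.ndarray) -> float | None:
    if len(a) == 0:
        return None
    return float(np.mean(np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))))


def sl_pd_errors(
    predictions: pd.DataFrame,
    truth: pd.DataFrame,
    condition: str = "model",
    sl_col: str = "rtw_days",
    pd_col: str = "pd_percent",
) -> ErrorReport:
    """MAE of sick-leave days and PD percent per severity split.

    ``predictions`` and ``truth`` are aligned on case_id; ``truth`` must
    carry class_label, true_sl_days and true_pd_percent.
    """
    merged = predictions.merge(truth, on="case_id", how="inner", validate="one_to_one")
    out: dict[str, float | None] = {}
    counts: dict[str, int] = {}
    for cls, tag in ((BLM, "blm"), (HLM, "hlm")):
        sub = merged.loc[merged["class_label"] == cls]
        counts[tag] = len(sub)
        if len(sub) == 0:
            warnings.warn(f"no {cls} cases in evaluation set; split absent", stacklevel=2)
            out[f"sl_{tag}"] = out[f"pd_{tag}"] = None
            continue
        out[f"sl_{tag}"] = _mae(sub[sl_col].to_numpy(), sub["true_sl_days"].to_numpy())
        if pd_col in sub:
            out[f"pd_{tag}"] = _mae(sub[pd_col].to_numpy(), sub["true_pd_percent"].to_numpy())
        else:
            out[f"pd_{tag}"] = None
    return ErrorReport(
        condition=condition,
        sl_mae_blm=out["sl_blm"],
        sl_mae_hlm=out["sl_hlm"],
        pd_mae_blm=out["pd_blm"],
        pd_mae_hlm=out["pd_hlm"],
        n_blm=counts["blm"],
        n_hlm=counts["hlm"],
    )


def select_human_estimates(logs: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Pick the comparison estimate per case from the change logs.

    Benign: earliest estimated_SL entry.  Serious: the entry nearest in
    time to the HLM day.  Cases without any estimate are excluded and
    counted in the ``n_excluded`` attribute of the result frame.
    """
    est = logs.loc[logs["field"] == "estimated_SL"].copy()
    est["day_offset"] = pd.to_numeric(est["day_offset"])
    est["value"] = pd.to_numeric(est["value"])
    pd_est = logs.loc[logs["field"] == "estimated_PD"].copy()
    if len(pd_est):
        pd_est["day_offset"] = pd.to_numeric(pd_est["day_offset"])
        pd_est["value"] = pd.to_numeric(pd_est["value"])
    rows, excluded = [], 0
    by_case = dict(tuple(est.groupby("case_id")))
    pd_by_case = dict(tuple(pd_est.groupby("case_id"))) if len(pd_est) else {}
    for row in truth.itertuples(index=False):
        entries = by_case.get(row.case_id)
        if entries is None or len(entries) == 0:
            excluded += 1
            continue
        if row.class_label == BLM or pd.isna(row.hlm_day):
            pick = entries.loc[entries["day_offset"].idxmin()]
        else:
            pick = entries.loc[(entries["day_offset"] - float(row.hlm_day)).abs().idxmin()]
        pd_entries = pd_by_case.get(row.case_id)
        if pd_entries is not None and len(pd_entries):
            pd_pick = float(
                pd_entries.loc[(pd_entries["day_offset"] - float(pick["day_offset"])).abs().idxmin(), "value"]
            )
        else:
            pd_pick = np.nan
        rows.append((row.case_id, float(pick["day_offset"]), float(pick["value"]), pd_pick))
    out = pd.DataFrame(rows, columns=["case_id", "day_offset", "rtw_days", "pd_percent"])
    out.attrs["n_excluded"] = excluded
    return out


def human_comparison(
    model_report: ErrorReport, logs: pd.DataFrame, truth: pd.DataFrame
) -> pd.DataFrame:
    """Model vs simulated-human error table with per-cell ratios."""
    human_est = select_human_estimates(logs, truth)
    human_report = sl_pd_errors(human_est, truth, condition="human")
    rows = [model_report.to_row(), human_report.to_row()]
    table = pd.DataFrame(rows).set_index("condition")
    ratio = {}
    for col in ("sl_mae_blm", "sl_mae_hlm", "pd_mae_blm", "pd_mae_hlm"):
        m, h = table.loc["model", col], table.loc["human", col]
        ratio[col] = (m / h) if (m is not None and h not in (None, 0) and not pd.isna(h)) else np.nan
    table.loc["model/human ratio"] = {**ratio, "n_blm": table.loc["model", "n_blm"], "n_hlm": table.loc["model", "n_hlm"]}
    table.attrs["n_excluded"] = human_est.attrs.get("n_excluded", 0)
    return table


@dataclass(frozen=True)
class StrategyAccuracyReport:
    split: str
    per_case_accuracy: np.ndarray
    per_strategy_recall: dict[str, float]
    per_strategy_precision: dict[str, float]
    n_cases: int
    n_excluded_empty_truth: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_case_accuracy)) if len(self.per_case_accuracy) else float("nan")


def strategy_accuracy(
    predicted: dict[str, set[str]],
    truth_sets: dict[str, set[str]],
    labels: dict[str, str],
) -> dict[str, StrategyAccuracyReport]:
    """Per-case and per-strategy accuracy, split by severity class.

    ``predicted`` maps case_id -> strategies surviving the >40% rule;
    ``truth_sets`` maps case_id -> ground-truth strategies; ``labels``
    maps case_id -> BLM/HLM.
    """
    reports = {}
    for cls in (BLM, HLM):
        ids = [cid for cid, lab in labels.items() if lab == cls and cid in truth_sets]
        per_case, excluded = [], 0
        hit: dict[str, int] = {}
        seen: dict[str, int] = {}
        pred_count: dict[str, int] = {}
        pred_hit: dict[str, int] = {}
        for cid in ids:
            truth = truth_sets[cid]
            pred = predicted.get(cid, set())
            for s in pred:
                pred_count[s] = pred_count.get(s, 0) + 1
                if s in truth:
                    pred_hit[s] = pred_hit.get(s, 0) + 1
            if not truth:
                excluded += 1
                continue
            per_case.append(len(pred & truth) / len(truth))
            for s in truth:
                seen[s] = seen.get(s, 0) + 1
                if s in pred:
                    hit[s] = hit.get(s, 0) + 1
        reports[cls] = StrategyAccuracyReport(
            split=cls,
            per_case_accuracy=np.array(per_case),
            per_strategy_recall={s: hit.get(s, 0) / n for s, n in sorted(seen.items())},
            per_strategy_precision={s: pred_hit.get(s, 0) / n for s, n in sorted(pred_count.items())},
            n_cases=len(per_case),
            n_excluded_empty_truth=excluded,
        )
    return reports


def report_table(reports: list[ErrorReport]) -> pd.DataFrame:
    """Stack error reports into the standard layout."""
    return pd.DataFrame([r.to_row() for r in reports]).set_index("condition")
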