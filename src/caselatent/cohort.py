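"""Seeded synthetic work-injury cohorts.

Real work-injury case files (static records plus the case managers' change
logs) are proprietary, so this module generates cohorts that carry the same
structure the downstream models assume: a benign (BLM) majority with short
sick leave, a serious high-level-management (HLM) minority with long sick
leave, permanent disability (PD) that grows with sick-leave duration,
strategy sets that grow with severity, and time-stamped change logs that
include noisy case-manager estimates of sick leave and PD.

The generator also returns the ground truth used to create each case, so
recovery experiments can measure how much of the planted signal the
pipeline retrieves.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

BLM = "BLM"
HLM = "HLM"

#: canonical column order of an emitted static record (17 modelled fields + id)
STATIC_COLUMNS = [
    "case_id",
    "age",
    "salary",
    "sl_total_days",
    "days_until_hlm",
    "alertness_score",
    "date_of_accident",
    "date_case_closed",
    "injured_body_parts",
    "nature_of_loss",
    "cause",
    "industry",
    "position",
    "physical_demand_level",
    "handling_frequency",
    "form7_pd",
    "blm_hlm_flag",
]

LOG_COLUMNS = ["case_id", "day_offset", "field", "value"]

#: strategy vocabulary with class-conditional occurrence weights.  Ordered so
#: that the population-marginal frequency is strictly decreasing; return to
#: work on full duties is by far the most common logged action.
DEFAULT_STRATEGY_PROFILE: dict[str, dict[str, float]] = {
    "RTW—Full Duties": {BLM: 0.95, HLM: 0.85},
    "RTW—Modified Duties": {BLM: 0.35, HLM: 0.60},
    "Physiotherapy": {BLM: 0.25, HLM: 0.70},
    "Occupational Therapy": {BLM: 0.10, HLM: 0.50},
    "Case Conference": {BLM: 0.05, HLM: 0.55},
    "Work Trial": {BLM: 0.02, HLM: 0.40},
    "IME": {BLM: 0.02, HLM: 0.35},
    "DS": {BLM: 0.01, HLM: 0.30},
    "Legal": {BLM: 0.01, HLM: 0.25},
}

#: categorical vocabularies with class-conditional sampling weights; serious
#: cases skew toward back injuries, fractures and heavy construction work.
DEFAULT_CATEGORY_VOCAB: dict[str, dict[str, list]] = {
    "injured_body_parts": {
        "levels": ["Back", "Shoulder", "Hand", "Finger", "Leg", "Head"],
        BLM: [0.15, 0.15, 0.25, 0.25, 0.15, 0.05],
        HLM: [0.40, 0.20, 0.10, 0.05, 0.15, 0.10],
    },
    "nature_of_loss": {
        "levels": ["Sprain", "Fracture", "Laceration", "Contusion", "Amputation"],
        BLM: [0.40, 0.10, 0.25, 0.24, 0.01],
        HLM: [0.20, 0.40, 0.10, 0.15, 0.15],
    },
    "cause": {
        "levels": ["Lifting", "Fall", "Struck by object", "Machinery", "Slip"],
        BLM: [0.25, 0.15, 0.25, 0.10, 0.25],
        HLM: [0.30, 0.30, 0.15, 0.15, 0.10],
    },
    "industry": {
        "levels": ["Construction", "Manufacturing", "Logistics", "Catering", "Office"],
        BLM: [0.15, 0.20, 0.20, 0.25, 0.20],
        HLM: [0.40, 0.25, 0.20, 0.10, 0.05],
    },
    "position": {
        "levels": ["Labourer", "Operator", "Driver", "Cook", "Clerk"],
        BLM: [0.20, 0.20, 0.20, 0.20, 0.20],
        HLM: [0.40, 0.25, 0.15, 0.10, 0.10],
    },
    "physical_demand_level": {
        "levels": ["Sedentary", "Light", "Medium", "Heavy"],
        BLM: [0.20, 0.30, 0.30, 0.20],
        HLM: [0.05, 0.15, 0.35, 0.45],
    },
    "handling_frequency": {
        "levels": ["Rarely", "Sometimes", "Often", "Constant"],
        BLM: [0.25, 0.30, 0.30, 0.15],
        HLM: [0.10, 0.20, 0.35, 0.35],
    },
}

#: additive effects on log sick-leave days by categorical level — the
#: recoverable signal the predictors are asked to retrieve.
DEFAULT_SL_COVARIATE_EFFECTS: dict[str, dict[str, float]] = {
    "industry": {
        "Construction": 0.25,
        "Manufacturing": 0.10,
        "Logistics": 0.00,
        "Catering": -0.10,
        "Office": -0.25,
    },
    "injured_body_parts": {
        "Back": 0.30,
        "Shoulder": 0.15,
        "Hand": 0.00,
        "Leg": 0.00,
        "Head": 0.10,
        "Finger": -0.20,
    },
}

_EPOCH = pd.Timestamp("2015-01-01")


class LogNormalParams(BaseModel):
    """Location/spread of log sick-leave days for one severity class."""

    mu: float
    sigma: float = Field(ge=0.0)

    model_config = ConfigDict(frozen=True)


class CohortConfig(BaseModel):
    """All knobs of the synthetic cohort, with validated defaults.

    Defaults describe a mixed cohort: 20% serious cases, benign sick leave
    around two weeks, serious sick leave around five months, and
    case-manager estimate noise calibrated so the simulated human errs on
    the scale reported for real case managers (mean absolute error around
    16 days benign / 155 days serious).
    """

    n_cases: int = Field(gt=0)
    hlm_fraction: float = Field(default=0.2, ge=0.0, le=1.0)
    sl_blm_params: LogNormalParams = LogNormalParams(mu=math.log(14.0), sigma=0.5)
    sl_hlm_params: LogNormalParams = LogNormalParams(mu=math.log(150.0), sigma=0.5)
    sl_covariate_effects: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SL_COVARIATE_EFFECTS.items()}
    )
    #: PD percent gained per 100 sick-leave days, by class
    pd_slope: dict[str, float] = Field(default_factory=lambda: {BLM: 0.5, HLM: 1.0})
    pd_noise_sd: dict[str, float] = Field(default_factory=lambda: {BLM: 0.05, HLM: 0.3})
    #: HLM is applied somewhere in this fraction of the case duration
    hlm_day_frac: tuple[float, float] = (0.1, 0.6)
    strategy_profile: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_STRATEGY_PROFILE.items()}
    )
    #: inclusive range of distinct strategies per case, by class
    strategy_count_range: dict[str, tuple[int, int]] = Field(
        default_factory=lambda: {BLM: (1, 2), HLM: (3, 8)}
    )
    category_vocab: dict[str, dict[str, list]] = Field(
        default_factory=lambda: {k: {kk: list(vv) for kk, vv in v.items()} for k, v in DEFAULT_CATEGORY_VOCAB.items()}
    )
    #: sd (days) of the simulated case manager's sick-leave estimate, by class
    human_noise_sd: dict[str, float] = Field(default_factory=lambda: {BLM: 20.5, HLM: 194.0})
    #: sd (percent) of the simulated case manager's PD estimate, by class
    pd_human_noise_sd: dict[str, float] = Field(default_factory=lambda: {BLM: 0.34, HLM: 2.64})
    seed: int = 0

    model_config = ConfigDict(frozen=True)

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        if not self.sl_hlm_params.mu > self.sl_blm_params.mu:
            raise ValueError("sl_hlm_params: serious log-location must exceed benign log-location")
        lo, hi = self.hlm_day_frac
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("hlm_day_frac: must satisfy 0 <= lo <= hi <= 1")
        for name, probs in self.strategy_profile.items():
            for cls in (BLM, HLM):
                p = probs.get(cls)
                if p is None or not (0.0 <= p <= 1.0):
                    raise ValueError(f"strategy_profile: probability for {name!r}/{cls} must be in [0,1]")
        h = self.hlm_fraction
        marginal = {
            name: (1.0 - h) * probs[BLM] + h * probs[HLM]
            for name, probs in self.strategy_profile.items()
        }
        top = max(marginal, key=marginal.get)
        if top != "RTW—Full Duties" and "RTW—Full Duties" in marginal:
            raise ValueError("strategy_profile: 'RTW—Full Duties' must have the highest marginal probability")
        for field, spec in self.category_vocab.items():
            levels = spec.get("levels", [])
            if len(set(levels)) != len(levels):
                raise ValueError(f"category_vocab: duplicate levels in {field!r}")
            for cls in (BLM, HLM):
                w = np.asarray(spec[cls], dtype=float)
                if len(w) != len(levels) or (w < 0).any() or w.sum() <= 0:
                    raise ValueError(f"category_vocab: bad {cls} weights for {field!r}")
        for cls, (lo_n, hi_n) in self.strategy_count_range.items():
            if not (1 <= lo_n <= hi_n <= len(self.strategy_profile)):
                raise ValueError(f"strategy_count_range: bad range for {cls}")
        return self


@dataclass
class Cohort:
    """A generated cohort: emitted data plus the truth that produced it."""

    static: pd.DataFrame
    logs: pd.DataFrame
    truth: pd.DataFrame
    config: CohortConfig

    def write(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "static": directory / "static.csv",
            "logs": directory / "dynamic_logs.csv",
            "truth": directory / "ground_truth.json",
        }
        self.static.to_csv(paths["static"], index=False)
        self.logs.to_csv(paths["logs"], index=False)
        paths["truth"].write_text(truth_to_json(self.truth))
        return paths


def truth_to_json(truth: pd.DataFrame) -> str:
    out = {}
    for row in truth.itertuples(index=False):
        out[row.case_id] = {
            "class_label": row.class_label,
            "true_sl_days": int(row.true_sl_days),
            "true_pd_percent": float(row.true_pd_percent),
            "hlm_day": None if pd.isna(row.hlm_day) else int(row.hlm_day),
            "strategies": json.loads(row.strategies),
            "human_estimate_sl": float(row.human_estimate_sl),
        }
    return json.dumps(out, indent=1, ensure_ascii=False, sort_keys=True)


def _sample_categories(rng: np.random.Generator, config: CohortConfig, labels: np.ndarray) -> dict[str, np.ndarray]:
    n = len(labels)
    out: dict[str, np.ndarray] = {}
    for field, spec in config.category_vocab.items():
        levels = np.asarray(spec["levels"], dtype=object)
        col = np.empty(n, dtype=object)
        for cls in (BLM, HLM):
            mask = labels == cls
            if not mask.any():
                continue
            w = np.asarray(spec[cls], dtype=float)
            w = w / w.sum()
            col[mask] = rng.choice(levels, size=int(mask.sum()), p=w)
        out[field] = col
    return out


def _covariate_log_effect(config: CohortConfig, cats: Mapping[str, np.ndarray], n: int) -> np.ndarray:
    eff = np.zeros(n)
    for field, table in config.sl_covariate_effects.items():
        col = cats.get(field)
        if col is None:
            continue
        eff += np.array([table.get(level, 0.0) for level in col])
    return eff


def _human_timeline(
    rng: np.random.Generator,
    cls: str,
    sl: int,
    hlm_day: float,
    true_pd: float,
    config: CohortConfig,
) -> list[tuple[int, float, float]]:
    """(day, est_sl, est_pd) revision entries for one case.

    Benign cases get one or two early estimates; serious cases are
    re-estimated several times across the case, so one revision always
    lands close to the HLM day.
    """
    sl_sd = config.human_noise_sd[cls]
    pd_sd = config.pd_human_noise_sd[cls]
    if cls == BLM:
        k = int(rng.integers(1, 3))
        days = rng.integers(0, max(1, min(14, sl)) + 1, size=k)
    else:
        k = int(rng.integers(3, 6))
        days = rng.integers(0, sl + 1, size=k)
        if not math.isnan(hlm_day):
            # guarantee an estimate near the HLM day for the comparison rule
            days[0] = int(np.clip(hlm_day + rng.integers(-3, 4), 0, sl))
    days = np.unique(days)
    entries = []
    for d in days:
        est_sl = max(0.0, sl + rng.normal(0.0, sl_sd))
        est_pd = max(0.0, true_pd + rng.normal(0.0, pd_sd))
        entries.append((int(d), round(float(est_sl), 1), round(float(est_pd), 3)))
    return entries


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a seeded cohort of static records, change logs and truth.

    Identical configs produce byte-identical CSV output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    labels = np.where(rng.random(n) < config.hlm_fraction, HLM, BLM)
    cats = _sample_categories(rng, config, labels)

    mu = np.where(labels == HLM, config.sl_hlm_params.mu, config.sl_blm_params.mu)
    sigma = np.where(labels == HLM, config.sl_hlm_params.sigma, config.sl_blm_params.sigma)
    log_sl = mu + _covariate_log_effect(config, cats, n) + sigma * rng.standard_normal(n)
    sl = np.maximum(1, np.round(np.exp(log_sl))).astype(int)

    slope = np.array([config.pd_slope[c] for c in labels])
    pd_noise = np.array([config.pd_noise_sd[c] for c in labels]) * rng.standard_normal(n)
    pd_pct = np.round(np.maximum(0.0, slope * sl / 100.0 + pd_noise), 3)

    lo, hi = config.hlm_day_frac
    hlm_day = np.full(n, np.nan)
    is_hlm = labels == HLM
    hlm_day[is_hlm] = np.clip(np.round(rng.uniform(lo, hi, size=int(is_hlm.sum())) * sl[is_hlm]), 0, sl[is_hlm])

    alert_mu = np.where(is_hlm, 7.0, 3.0)
    alertness = np.round(np.clip(alert_mu + 1.5 * rng.standard_normal(n), 0.0, 10.0), 2)
    age = np.clip(np.round(40 + 12 * rng.standard_normal(n)), 18, 65).astype(int)
    salary = np.round(np.exp(rng.normal(math.log(18000.0), 0.4, size=n)) / 100).astype(int) * 100
    doa_offset = rng.integers(0, 2190, size=n)
    doa = _EPOCH + pd.to_timedelta(doa_offset, unit="D")
    closed = doa + pd.to_timedelta(sl, unit="D")

    case_ids = [f"C{idx:06d}" for idx in range(n)]

    # strategies: per-case target count drawn from the class range, then that
    # many distinct strategies sampled in proportion to the class profile
    names = list(config.strategy_profile)
    strat_rows: list[tuple[str, int, str, str]] = []
    truth_strategies: list[dict[str, int]] = []
    for i in range(n):
        cls = labels[i]
        lo_n, hi_n = config.strategy_count_range[cls]
        count = int(rng.integers(lo_n, hi_n + 1))
        w = np.array([config.strategy_profile[s][cls] for s in names], dtype=float)
        w = w / w.sum()
        chosen = rng.choice(names, size=count, replace=False, p=w)
        days = rng.integers(0, sl[i] + 1, size=count)
        case_strats = {str(s): int(d) for s, d in zip(chosen, days)}
        truth_strategies.append(case_strats)
        for s, d in sorted(case_strats.items()):
            strat_rows.append((case_ids[i], d, "strategy", s))

    est_rows: list[tuple[str, int, str, str]] = []
    human_first: list[float] = []
    human_selected: list[float] = []
    for i in range(n):
        entries = _human_timeline(rng, labels[i], int(sl[i]), float(hlm_day[i]), float(pd_pct[i]), config)
        for d, est_sl, est_pd in entries:
            est_rows.append((case_ids[i], d, "estimated_SL", f"{est_sl}"))
            est_rows.append((case_ids[i], d, "estimated_PD", f"{est_pd}"))
        if labels[i] == BLM:
            sel = entries[0][1]  # first estimate made
        else:
            sel = min(entries, key=lambda e: abs(e[0] - hlm_day[i]))[1]  # nearest to HLM day
        human_first.append(entries[0][1])
        human_selected.append(sel)

    static = pd.DataFrame(
        {
            "case_id": case_ids,
            "age": age,
            "salary": salary,
            "sl_total_days": sl,
            "days_until_hlm": pd.array(
                [int(d) if not math.isnan(d) else pd.NA for d in hlm_day], dtype="Int64"
            ),
            "alertness_score": alertness,
            "date_of_accident": doa.strftime("%Y-%m-%d"),
            "date_case_closed": closed.strftime("%Y-%m-%d"),
            **cats,
            "form7_pd": pd_pct,
            "blm_hlm_flag": labels,
        }
    )[STATIC_COLUMNS]

    logs = pd.DataFrame(strat_rows + est_rows, columns=LOG_COLUMNS)
    logs = logs.sort_values(["case_id", "day_offset", "field", "value"], kind="mergesort").reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "case_id": case_ids,
            "class_label": labels,
            "true_sl_days": sl,
            "true_pd_percent": pd_pct,
            "hlm_day": hlm_day,
            "strategies": [json.dumps(s, sort_keys=True, ensure_ascii=False) for s in truth_strategies],
            "human_estimate_sl": human_selected,
            "human_first_estimate_sl": human_first,
        }
    )
    return Cohort(static=static, logs=logs, truth=truth, config=config)


#: columns that inject_missingness may blank — ids, the class flag and the
#: (structurally absent for BLM) HLM day are protected
BLANKABLE_COLUMNS = [
    c for c in STATIC_COLUMNS if c not in ("case_id", "blm_hlm_flag", "days_until_hlm")
]


def inject_missingness(static: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Blank each blankable cell independently with probability ``rate``."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate: must lie in [0, 1)")
    out = static.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random((len(out), len(BLANKABLE_COLUMNS))) < rate
    for j, col in enumerate(BLANKABLE_COLUMNS):
        col_vals = out[col].astype(object)
        col_vals[mask[:, j]] = pd.NA
        out[col] = col_vals
    return out


def simulate_human_estimates(truth: pd.DataFrame, config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Per-case noisy case-manager estimates of SL and PD.

    Estimates are the true value plus zero-centred Gaussian noise with the
    class's ``human_noise_sd`` (days) / ``pd_human_noise_sd`` (percent),
    truncated at zero.  Returns one row per case with the estimate the
    human-comparison rule would select (benign: first made; serious: the
    one nearest the HLM day).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    for row in truth.itertuples(index=False):
        cls = row.class_label
        hlm_day = float(row.hlm_day) if not pd.isna(row.hlm_day) else float("nan")
        entries = _human_timeline(rng, cls, int(row.true_sl_days), hlm_day, float(row.true_pd_percent), config)
        if cls == BLM:
            sel = entries[0]
        else:
            sel = min(entries, key=lambda e: abs(e[0] - hlm_day)) if not math.isnan(hlm_day) else entries[0]
        rows.append((row.case_id, sel[0], sel[1], sel[2]))
    return pd.DataFrame(rows, columns=["case_id", "day_offset", "estimated_sl", "estimated_pd"])
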