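"""Reading, cleaning and encoding of static case records.

The modelling convention: continuous fields become standard scores
(training-split statistics, sample sd), categorical fields become one-hot
blocks, and every case carries two dynamic components — the number of days
passed since the accident and, when known, the day high-level management
was applied.  Records with missing values are dropped outright rather than
imputed, since mean replacement distorts the duration signal the model is
asked to learn.

Day-valued dynamic inputs (day passed, HLM day) are standardized with the
sick-leave scaler so that "day 30" means the same thing wherever it enters
the network.  An absent HLM day is encoded as a zero in standardized space
plus a binary "HLM applied" indicator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import BLM, HLM, STATIC_COLUMNS

CONTINUOUS_FIELDS = ["age", "salary", "sl_total_days", "alertness_score", "form7_pd"]
CATEGORICAL_FIELDS = [
    "injured_body_parts",
    "nature_of_loss",
    "cause",
    "industry",
    "position",
    "physical_demand_level",
    "handling_frequency",
]
DATE_FIELDS = ["date_of_accident", "date_case_closed"]

#: static covariates fed to the encoder (outcome fields are decoder-only)
INPUT_CONTINUOUS = ["age", "salary", "alertness_score"]
#: extra continuous fields the decoder reconstructs
OUTPUT_ONLY_CONTINUOUS = ["sl_total_days", "form7_pd"]
DYNAMIC_FIELDS = ["day_passed", "hlm_day", "hlm_applied"]

OTHER_LEVEL = "__other__"


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class ZeroVarianceError(ValueError):
    """A continuous field has no variance and cannot be standardized."""


def load_static(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Read a static-record CSV; returns (records, problem descriptions).

    Rows violating record invariants (close date before accident, negative
    sick leave or PD, HLM day inconsistent with the class flag) are kept in
    the frame but reported, so callers can decide whether to drop them.
    """
    df = pd.read_csv(path, dtype={"case_id": str})
    missing = [c for c in STATIC_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"static CSV is missing mandatory columns: {missing}")
    # the HLM day is structurally absent for benign cases; keep it integer
    df["days_until_hlm"] = pd.array(
        pd.to_numeric(df["days_until_hlm"], errors="coerce").round(), dtype="Int64"
    )
    problems: list[str] = []
    doa = pd.to_datetime(df["date_of_accident"], errors="coerce")
    closed = pd.to_datetime(df["date_case_closed"], errors="coerce")
    for i in df.index[(closed - doa).dt.days < 0]:
        problems.append(f"row {i}: date_case_closed precedes date_of_accident")
    for i in df.index[pd.to_numeric(df["sl_total_days"], errors="coerce") < 0]:
        problems.append(f"row {i}: negative sl_total_days")
    for i in df.index[pd.to_numeric(df["form7_pd"], errors="coerce") < 0]:
        problems.append(f"row {i}: negative form7_pd")
    hlm_day = pd.to_numeric(df["days_until_hlm"], errors="coerce")
    is_hlm = df["blm_hlm_flag"] == HLM
    for i in df.index[is_hlm & hlm_day.isna()]:
        problems.append(f"row {i}: HLM case without days_until_hlm")
    for i in df.index[(~is_hlm) & hlm_day.notna()]:
        problems.append(f"row {i}: BLM case with days_until_hlm set")
    sl = pd.to_numeric(df["sl_total_days"], errors="coerce")
    for i in df.index[is_hlm & (hlm_day > sl)]:
        problems.append(f"row {i}: days_until_hlm exceeds sl_total_days")
    return df, problems


def load_logs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"case_id": str, "field": str, "value": str})
    for col in ("case_id", "day_offset", "field", "value"):
        if col not in df.columns:
            raise SchemaError(f"log CSV is missing mandatory column: {col}")
    if (pd.to_numeric(df["day_offset"], errors="coerce") < 0).any():
        raise SchemaError("log CSV contains negative day_offset")
    return df


def drop_incomplete(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Whole-record drop of any row with a missing modelled field.

    ``days_until_hlm`` is exempt for benign cases, where its absence is
    structural rather than missing data.  Returns (survivors, n_dropped).
    Idempotent.
    """
    required = [c for c in STATIC_COLUMNS if c != "days_until_hlm"]
    ok = records[required].notna().all(axis=1)
    is_hlm = records["blm_hlm_flag"] == HLM
    ok &= ~(is_hlm & records["days_until_hlm"].isna())
    survivors = records.loc[ok].reset_index(drop=True)
    return survivors, int((~ok).sum())


def split_train_test(
    records: pd.DataFrame, ratio: float = 0.05, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded disjoint split; the test set holds round(ratio * n) records."""
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    if not (0.0 < ratio < 1.0):
        raise ValueError("ratio: must lie in (0, 1)")
    n_test = int(np.floor(ratio * n + 0.5))  # round half-up
    n_test = min(max(n_test, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return (
        records.iloc[train_idx].reset_index(drop=True),
        records.iloc[test_idx].reset_index(drop=True),
    )


@dataclass(frozen=True)
class ScalerParams:
    """Per-field mean and sample standard deviation (n-1 denominator)."""

    means: dict[str, float]
    sds: dict[str, float]

    def transform(self, field_name: str, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.means[field_name]) / self.sds[field_name]

    def inverse(self, field_name: str, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) * self.sds[field_name] + self.means[field_name]

    def to_dict(self) -> dict:
        return {"means": self.means, "sds": self.sds}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerParams":
        return cls(means=dict(d["means"]), sds=dict(d["sds"]))


def fit_scaler(records: pd.DataFrame, fields: list[str] | None = None) -> ScalerParams:
    """Estimate standard-score parameters on the training split only."""
    fields = CONTINUOUS_FIELDS if fields is None else fields
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for f in fields:
        col = pd.to_numeric(records[f], errors="coerce").dropna().to_numpy(dtype=float)
        if len(col) < 2:
            raise ZeroVarianceError(f"field {f!r}: need at least 2 values to standardize")
        sd = float(np.std(col, ddof=1))
        if sd == 0.0:
            raise ZeroVarianceError(f"field {f!r}: zero variance in training split")
        means[f] = float(np.mean(col))
        sds[f] = sd
    return ScalerParams(means=means, sds=sds)


@dataclass(frozen=True)
class CategoryVocabulary:
    """Ordered level lists per categorical field, with one-hot arithmetic.

    Unless ``strict``, an explicit catch-all level is appended to every
    field so unseen levels at inference map somewhere well-defined.
    """

    levels: dict[str, list[str]]
    strict: bool = False

    @classmethod
    def fit(cls, records: pd.DataFrame, fields: list[str] | None = None, strict: bool = False) -> "CategoryVocabulary":
        fields = CATEGORICAL_FIELDS if fields is None else fields
        levels = {}
        for f in fields:
            obs = sorted(records[f].dropna().astype(str).unique().tolist())
            if not strict:
                obs = obs + [OTHER_LEVEL]
            levels[f] = obs
        return cls(levels=levels, strict=strict)

    @property
    def fields(self) -> list[str]:
        return list(self.levels)

    def width(self, field_name: str) -> int:
        return len(self.levels[field_name])

    @property
    def total_width(self) -> int:
        return sum(len(v) for v in self.levels.values())

    def index_of(self, field_name: str, level: str) -> int:
        lv = self.levels[field_name]
        try:
            return lv.index(str(level))
        except ValueError:
            if self.strict:
                raise KeyError(f"unknown level {level!r} for field {field_name!r} (strict vocabulary)")
            return lv.index(OTHER_LEVEL)

    def encode_column(self, field_name: str, values: pd.Series) -> np.ndarray:
        idx = np.array([self.index_of(field_name, v) for v in values.astype(str)])
        out = np.zeros((len(idx), self.width(field_name)))
        out[np.arange(len(idx)), idx] = 1.0
        return out

    def decode_index(self, field_name: str, index: int) -> str:
        return self.levels[field_name][index]

    def to_dict(self) -> dict:
        return {"levels": self.levels, "strict": self.strict}

    @classmethod
    def from_dict(cls, d: dict) -> "CategoryVocabulary":
        return cls(levels={k: list(v) for k, v in d["levels"].items()}, strict=bool(d["strict"]))


@dataclass(frozen=True)
class FeatureVector:
    """One encoded case at one time point."""

    static_continuous: np.ndarray
    static_categorical: np.ndarray
    dynamic: np.ndarray  # (day_passed, hlm_day, hlm_applied), standardized


@dataclass(frozen=True)
class EncodedBatch:
    """Column blocks for a batch of cases, ready for the network.

    ``x_cont`` columns follow ``codec.cont_input_fields``; ``x_cat`` is the
    concatenation of one-hot groups in ``codec.cat_fields`` order.
    Decoder targets add the outcome fields (see ``codec``).
    """

    x_cont: np.ndarray
    x_cat: np.ndarray
    y_cont: np.ndarray | None = None
    y_cat_idx: np.ndarray | None = None  # (n, n_groups) int level indices


@dataclass(frozen=True)
class FeatureCodec:
    """Bundles scaler + vocabulary + field layout into one encode/decode unit.

    The encoder side sees static covariates plus the dynamic components;
    the decoder side additionally reconstructs sick leave, PD and the
    BLM/HLM flag, which is how the network reads an endpoint back out of a
    latent point.
    """

    scaler: ScalerParams
    vocab: CategoryVocabulary
    use_alertness: bool = True

    @property
    def cont_static_fields(self) -> list[str]:
        fields = list(INPUT_CONTINUOUS)
        if not self.use_alertness:
            fields.remove("alertness_score")
        return fields

    @property
    def cont_input_fields(self) -> list[str]:
        return self.cont_static_fields + DYNAMIC_FIELDS

    @property
    def cont_output_fields(self) -> list[str]:
        return self.cont_input_fields + OUTPUT_ONLY_CONTINUOUS

    @property
    def cat_fields(self) -> list[str]:
        return self.vocab.fields

    @property
    def cat_output_groups(self) -> list[tuple[str, int]]:
        return [(f, self.vocab.width(f)) for f in self.cat_fields] + [("blm_hlm_flag", 2)]

    @property
    def n_cont_in(self) -> int:
        return len(self.cont_input_fields)

    @property
    def n_cont_out(self) -> int:
        return len(self.cont_output_fields)

    @property
    def cat_in_width(self) -> int:
        return self.vocab.total_width

    def _day_scale(self, days: np.ndarray) -> np.ndarray:
        return self.scaler.transform("sl_total_days", days)

    def _day_unscale(self, z: np.ndarray) -> np.ndarray:
        return self.scaler.inverse("sl_total_days", z)

    def encode_frame(
        self,
        records: pd.DataFrame,
        day_passed: np.ndarray,
        hlm_day: np.ndarray | None = None,
        with_targets: bool = False,
    ) -> EncodedBatch:
        """Encode records at per-case time points.

        ``hlm_day`` entries of NaN mean "HLM not (yet) applied" and are
        encoded as the sentinel (0 in standardized space) plus a zero
        indicator.
        """
        n = len(records)
        day_passed = np.asarray(day_passed, dtype=float)
        if (day_passed < 0).any():
            raise ValueError("day_passed: must be non-negative")
        if hlm_day is None:
            hlm_day = np.full(n, np.nan)
        hlm_day = np.asarray(hlm_day, dtype=float)
        applied = (~np.isnan(hlm_day)).astype(float)
        hlm_scaled = np.where(np.isnan(hlm_day), 0.0, self._day_scale(np.nan_to_num(hlm_day)))

        cont_cols = [
            self.scaler.transform(f, pd.to_numeric(records[f]).to_numpy(dtype=float))
            for f in self.cont_static_fields
        ]
        cont_cols += [self._day_scale(day_passed), hlm_scaled, applied]
        x_cont = np.column_stack(cont_cols)
        x_cat = np.concatenate(
            [self.vocab.encode_column(f, records[f]) for f in self.cat_fields], axis=1
        )

        y_cont = y_cat = None
        if with_targets:
            extra = [
                self.scaler.transform(f, pd.to_numeric(records[f]).to_numpy(dtype=float))
                for f in OUTPUT_ONLY_CONTINUOUS
            ]
            y_cont = np.column_stack([x_cont] + [np.column_stack(extra)]) if extra else x_cont
            cat_idx = [
                np.array([self.vocab.index_of(f, v) for v in records[f].astype(str)])
                for f in self.cat_fields
            ]
            cat_idx.append((records["blm_hlm_flag"] == HLM).to_numpy().astype(int))
            y_cat = np.column_stack(cat_idx)
        return EncodedBatch(x_cont=x_cont, x_cat=x_cat, y_cont=y_cont, y_cat_idx=y_cat)

    def encode_record(
        self, record: pd.Series | dict, day_passed: float, hlm_day: float | None = None
    ) -> FeatureVector:
        """Build the {C_s, t} feature vector for one case at day ``t``."""
        if day_passed < 0:
            raise ValueError("day_passed: must be non-negative")
        frame = pd.DataFrame([record])
        hd = np.array([np.nan if hlm_day is None else float(hlm_day)])
        batch = self.encode_frame(frame, np.array([float(day_passed)]), hd)
        return FeatureVector(
            static_continuous=batch.x_cont[0, : len(self.cont_static_fields)],
            static_categorical=batch.x_cat[0],
            dynamic=batch.x_cont[0, len(self.cont_static_fields):],
        )

    def decode_outputs(self, y_cont: np.ndarray, cat_probs: list[np.ndarray]) -> pd.DataFrame:
        """Map network outputs back to natural units and level names.

        Continuous fields are de-standardized; sick leave and PD are
        clipped at zero; each categorical group is reported as its
        highest-probability level (full probability vectors are available
        to callers that keep ``cat_probs``).
        """
        out: dict[str, np.ndarray] = {}
        for j, f in enumerate(self.cont_output_fields):
            if f in ("day_passed", "hlm_day"):
                out[f] = self._day_unscale(y_cont[:, j])
            elif f == "hlm_applied":
                out[f] = (y_cont[:, j] > 0.5).astype(float)
            else:
                out[f] = self.scaler.inverse(f, y_cont[:, j])
        out["sl_total_days"] = np.maximum(0.0, out["sl_total_days"])
        out["form7_pd"] = np.maximum(0.0, out["form7_pd"])
        for (f, width), probs in zip(self.cat_output_groups, cat_probs):
            idx = probs.argmax(axis=1)
            if f == "blm_hlm_flag":
                out[f] = np.where(idx == 1, HLM, BLM)
            else:
                out[f] = np.array([self.vocab.decode_index(f, i) for i in idx], dtype=object)
        return pd.DataFrame(out)

    def to_json(self) -> str:
        return json.dumps(
            {
                "scaler": self.scaler.to_dict(),
                "vocab": self.vocab.to_dict(),
                "use_alertness": self.use_alertness,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureCodec":
        d = json.loads(text)
        return cls(
            scaler=ScalerParams.from_dict(d["scaler"]),
            vocab=CategoryVocabulary.from_dict(d["vocab"]),
            use_alertness=bool(d["use_alertness"]),
        )


def fit_codec(train_records: pd.DataFrame, use_alertness: bool = True, strict: bool = False) -> FeatureCodec:
    """Fit scaler and vocabulary on the training split only."""
    scaler = fit_scaler(train_records)
    vocab = CategoryVocabulary.fit(train_records, strict=strict)
    return FeatureCodec(scaler=scaler, vocab=vocab, use_alertness=use_alertness)
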