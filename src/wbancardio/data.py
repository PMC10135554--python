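"""Synthetic vital-sign dataset: generation, threshold labeling, splits, CSV I/O.

The dataset emulates wearable-sensor health records: each individual contributes
three vitals — oxygen saturation (%), respiratory rate (breaths/min) and heart
rate (bpm) — and a binary disease label derived deterministically from fixed
screening thresholds (oxygen < 92, respiratory > 53, heartbeat < 100; strict
inequalities). The default combination rule flags a record as positive when ANY
single vital is abnormal; AND and single-attribute rules are also available.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

ATTRIBUTES = ("oxygen", "respiratory", "heartbeat")

#: Screening thresholds: (attribute, direction). "below" means value < threshold
#: is abnormal; "above" means value > threshold is abnormal. Strict comparisons.
THRESHOLDS = {
    "oxygen": (92.0, "below"),
    "respiratory": (53.0, "above"),
    "heartbeat": (100.0, "below"),
}

LABEL_RULES = ("any", "all", "oxygen", "respiratory", "heartbeat")

DEFAULT_RANGES = {
    "oxygen": (80.0, 100.0),
    "respiratory": (20.0, 80.0),
    "heartbeat": (60.0, 200.0),
}


class ValidationError(ValueError):
    """A record or spec failed validation."""


class ParseError(ValueError):
    """A CSV row could not be parsed."""


@dataclass(frozen=True)
class VitalRecord:
    """One individual's vitals plus the binary disease label."""

    oxygen: float
    respiratory: float
    heartbeat: float
    label: int

    def __post_init__(self) -> None:
        for name in ATTRIBUTES:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ValidationError(f"attribute {name!r} is missing or non-finite: {v!r}")
        if self.label not in (0, 1):
            raise ValidationError(f"label must be 0 or 1, got {self.label!r}")


@dataclass(frozen=True)
class DatasetSpec:
    """Parameters of the synthetic cohort.

    ``n_records`` individuals, each vital drawn independently within its
    ``ranges`` entry (uniform by default, or truncated normal centred on the
    range midpoint with ``distribution='truncnorm'``). ``seed`` fixes the
    drawn dataset bit-exactly. ``positive_fraction_target``, when set, draws
    records by rejection until the requested class counts are met.
    """

    n_records: int = 1000
    ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    seed: int = 0
    rule: str = "any"
    distribution: str = "uniform"
    positive_fraction_target: float | None = None

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValidationError("n_records must be >= 1")
        if self.rule not in LABEL_RULES:
            raise ValidationError(f"unknown label rule {self.rule!r}")
        if self.distribution not in ("uniform", "truncnorm"):
            raise ValidationError(f"unknown distribution {self.distribution!r}")
        for name in ATTRIBUTES:
            lo, hi = self.ranges[name]
            if not lo < hi:
                raise ValidationError(f"degenerate range for {name}: [{lo}, {hi}]")
        if self.positive_fraction_target is not None and not (
            0.0 <= self.positive_fraction_target <= 1.0
        ):
            raise ValidationError("positive_fraction_target must be in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DatasetSpec":
        d = json.loads(text)
        d["ranges"] = {k: tuple(v) for k, v in d["ranges"].items()}
        return cls(**d)


def _is_abnormal(name: str, value: float) -> bool:
    thr, direction = THRESHOLDS[name]
    return value < thr if direction == "below" else value > thr


def label_record(
    oxygen: float, respiratory: float, heartbeat: float, rule: str = "any"
) -> int:
    """Apply the threshold rule to one record's vitals; returns 0 or 1.

    ``rule='any'`` (default): positive iff at least one vital is abnormal.
    ``rule='all'``: positive iff all three are abnormal. A single attribute
    name restricts the rule to that vital alone.
    """
    values = {"oxygen": oxygen, "respiratory": respiratory, "heartbeat": heartbeat}
    for name, v in values.items():
        if v is None or not math.isfinite(v):
            raise ValidationError(f"attribute {name!r} is missing or non-finite: {v!r}")
    flags = {name: _is_abnormal(name, v) for name, v in values.items()}
    if rule == "any":
        return int(any(flags.values()))
    if rule == "all":
        return int(all(flags.values()))
    if rule in flags:
        return int(flags[rule])
    raise ValidationError(f"unknown label rule {rule!r}")


def label_frame(df: pd.DataFrame, rule: str = "any") -> np.ndarray:
    """Vectorized labeling of a dataframe with the three attribute columns."""
    vals = df[list(ATTRIBUTES)].to_numpy(float)
    if not np.isfinite(vals).all():
        bad = [a for i, a in enumerate(ATTRIBUTES) if not np.isfinite(vals[:, i]).all()]
        raise ValidationError(f"non-finite values in attribute(s) {bad}")
    flags = np.column_stack(
        [
            vals[:, 0] < THRESHOLDS["oxygen"][0],
            vals[:, 1] > THRESHOLDS["respiratory"][0],
            vals[:, 2] < THRESHOLDS["heartbeat"][0],
        ]
    )
    if rule == "any":
        return flags.any(axis=1).astype(int)
    if rule == "all":
        return flags.all(axis=1).astype(int)
    if rule in ATTRIBUTES:
        return flags[:, ATTRIBUTES.index(rule)].astype(int)
    raise ValidationError(f"unknown label rule {rule!r}")


def _draw(spec: DatasetSpec, n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for name in ATTRIBUTES:
        lo, hi = spec.ranges[name]
        if spec.distribution == "uniform":
            cols[name] = rng.uniform(lo, hi, size=n)
        else:
            # truncated normal centred on the range midpoint, sd = range/4
            mu, sd = (lo + hi) / 2.0, (hi - lo) / 4.0
            a, b = (lo - mu) / sd, (hi - mu) / sd
            cols[name] = stats.truncnorm.rvs(
                a, b, loc=mu, scale=sd, size=n, random_state=rng
            )
    return pd.DataFrame(cols)


def generate_dataset(spec: DatasetSpec) -> pd.DataFrame:
    """Generate the synthetic cohort as a dataframe with a ``label`` column.

    Identical spec (including seed) yields a bit-identical dataframe.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.positive_fraction_target is None:
        df = _draw(spec, spec.n_records, rng)
        df["label"] = label_frame(df, spec.rule)
        return df
    n_pos = int(round(spec.positive_fraction_target * spec.n_records))
    n_neg = spec.n_records - n_pos
    pos_rows, neg_rows = [], []
    # rejection sampling per class; bail out if a class is unreachable
    for _ in range(10_000):
        if len(pos_rows) >= n_pos and len(neg_rows) >= n_neg:
            break
        batch = _draw(spec, max(spec.n_records, 256), rng)
        batch["label"] = label_frame(batch, spec.rule)
        pos_rows.append(batch[batch.label == 1])
        neg_rows.append(batch[batch.label == 0])
        pos_rows = [pd.concat(pos_rows).head(n_pos)]
        neg_rows = [pd.concat(neg_rows).head(n_neg)]
        if len(pos_rows[0]) + len(neg_rows[0]) == spec.n_records:
            break
    pos, neg = pos_rows[0], neg_rows[0]
    if len(pos) < n_pos or len(neg) < n_neg:
        raise ValidationError(
            "positive_fraction_target unreachable under the configured ranges"
        )
    out = pd.concat([pos, neg]).sample(frac=1.0, random_state=int(rng.integers(2**31)))
    return out.reset_index(drop=True)


def analytic_positive_fraction(spec: DatasetSpec) -> float:
    """Closed-form P(positive) for uniform ranges under the OR rule.

    Inclusion–exclusion over the three independent per-attribute abnormality
    probabilities; only defined for ``distribution='uniform'`` and ``rule='any'``.
    """
    if spec.distribution != "uniform" or spec.rule != "any":
        raise ValidationError("closed form requires uniform sampling and the OR rule")
    p = []
    for name in ATTRIBUTES:
        lo, hi = spec.ranges[name]
        thr, direction = THRESHOLDS[name]
        if direction == "below":
            frac = (min(max(thr, lo), hi) - lo) / (hi - lo)
        else:
            frac = (hi - min(max(thr, lo), hi)) / (hi - lo)
        p.append(min(max(frac, 0.0), 1.0))
    q = 1.0
    for pi in p:
        q *= 1.0 - pi
    return 1.0 - q


def kfold_split(
    n_or_df, k: int, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded shuffled k-fold partition; returns (train_idx, test_idx) pairs.

    Folds are disjoint, cover all records, and differ in size by at most one.
    """
    from sklearn.model_selection import KFold

    n = n_or_df if isinstance(n_or_df, (int, np.integer)) else len(n_or_df)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > n:
        raise ValidationError(f"k={k} exceeds the number of records n={n}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr.copy(), te.copy()) for tr, te in kf.split(np.arange(n))]


def learning_percentage_split(
    n_or_df, percent: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Single seeded holdout split with |train| = round(percent/100 * n)."""
    n = n_or_df if isinstance(n_or_df, (int, np.integer)) else len(n_or_df)
    if not 0.0 < percent < 100.0:
        raise ValidationError("percent must be strictly between 0 and 100")
    n_train = int(round(percent / 100.0 * n))
    perm = np.random.default_rng(seed).permutation(n)
    return perm[:n_train], perm[n_train:]


def write_csv(df: pd.DataFrame, path) -> None:
    cols = [c for c in (*ATTRIBUTES, "label") if c in df.columns]
    df[cols].to_csv(path, index=False, float_format="%.17g")


def read_csv(path) -> pd.DataFrame:
    """Read a vitals CSV (header oxygen,respiratory,heartbeat[,label]).

    Raises :class:`ParseError` naming the offending 1-based data row on any
    non-numeric cell; an empty file with only a header is a valid empty dataset.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ATTRIBUTES if c not in df.columns]
    if missing:
        raise ParseError(f"missing required column(s) {missing}")
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ParseError(
                f"non-numeric value {df[col][bad.idxmax()]!r} in column {col!r} at data row {row}"
            )
        if converted.isna().any():
            row = int(converted.isna().idxmax()) + 1
            raise ParseError(f"missing value in column {col!r} at data row {row}")
        out[col] = converted
    res = pd.DataFrame(out)
    if "label" in res.columns:
        res["label"] = res["label"].astype(int)
    return res


def records_to_frame(records: Sequence[VitalRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def frame_to_records(df: pd.DataFrame) -> list[VitalRecord]:
    return [
        VitalRecord(r.oxygen, r.respiratory, r.heartbeat, int(r.label))
        for r in df.itertuples()
    ]
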