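"""AAMI-style evaluation: confusion matrices, Se/PP/Acc/Ave, report tables.

Every reported percentage is recomputed from a confusion matrix; nothing is
stored that could disagree with its own matrix. Reference (true) classes are
rows; algorithm (predicted) classes are columns. The final hierarchical
system only ever emits N, S, or V, so final-stage matrices have three
columns and reference F/Q beats can never be counted correct — they still
count in the accuracy denominator, as the AAMI protocol requires.

Undefined metrics (zero denominator) are ``None`` in Python, ``null`` in
JSON and ``-`` in formatted tables. Display rounding is half-up to one
decimal; internal comparisons always use full precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import AAMI_CLASSES, FINAL_CLASSES

__all__ = [
    "ConfusionMatrix",
    "sensitivity",
    "positive_predictive_value",
    "accuracy",
    "compute_ave",
    "ave_from_rates",
    "stage2_input_count",
    "per_recording_report",
    "round_half_up",
    "format_report",
]


def round_half_up(x: float | None, ndigits: int = 1) -> float | None:
    """Round half away from zero (the convention of the printed tables)."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return None
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class ConfusionMatrix:
    """Reference-class x algorithm-class count table."""

    def __init__(
        self,
        counts: pd.DataFrame | np.ndarray,
        row_classes: Sequence[str] = AAMI_CLASSES,
        col_classes: Sequence[str] | None = None,
    ) -> None:
        if isinstance(counts, pd.DataFrame):
            self.table = counts.astype(int).copy()
        else:
            if col_classes is None:
                col_classes = row_classes
            self.table = pd.DataFrame(
                np.asarray(counts, dtype=int),
                index=list(row_classes),
                columns=list(col_classes),
            )
        if (self.table.to_numpy() < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_labels(
        cls,
        reference: Iterable[str],
        algorithm: Iterable[str],
        row_classes: Sequence[str] = AAMI_CLASSES,
        col_classes: Sequence[str] = FINAL_CLASSES,
    ) -> "ConfusionMatrix":
        ref = np.asarray(list(reference), dtype=object)
        alg = np.asarray(list(algorithm), dtype=object)
        if len(ref) != len(alg):
            raise ValueError("reference and algorithm labels differ in length")
        unknown = set(ref) - set(row_classes)
        if unknown:
            raise ValueError(f"reference labels outside row classes: {unknown}")
        unknown = set(alg) - set(col_classes)
        if unknown:
            raise ValueError(f"algorithm labels outside column classes: {unknown}")
        counts = pd.DataFrame(
            0, index=list(row_classes), columns=list(col_classes), dtype=int
        )
        for r, a in zip(ref, alg):
            counts.loc[r, a] += 1
        return cls(counts)

    # -- structure ---------------------------------------------------------
    @property
    def row_classes(self) -> list[str]:
        return list(self.table.index)

    @property
    def col_classes(self) -> list[str]:
        return list(self.table.columns)

    @property
    def grand_total(self) -> int:
        return int(self.table.to_numpy().sum())

    def row_total(self, cls_: str) -> int:
        return int(self.table.loc[cls_].sum())

    def col_total(self, cls_: str) -> int:
        return int(self.table[cls_].sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if (
            self.row_classes != other.row_classes
            or self.col_classes != other.col_classes
        ):
            raise ValueError("cannot add confusion matrices with different classes")
        return ConfusionMatrix(self.table + other.table)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ConfusionMatrix) and self.table.equals(other.table)

    def __repr__(self) -> str:
        return f"ConfusionMatrix(\n{self.table}\n)"

    # -- metrics -----------------------------------------------------------
    def sensitivity(self, cls_: str) -> float | None:
        """100 * TP / reference-class total; None if the class never occurs."""
        total = self.row_total(cls_)
        if total == 0:
            return None
        tp = int(self.table.loc[cls_, cls_]) if cls_ in self.col_classes else 0
        return 100.0 * tp / total

    def positive_predictive_value(self, cls_: str) -> float | None:
        """100 * TP / algorithm-class total; None if the class is never emitted."""
        total = self.col_total(cls_)
        if total == 0:
            return None
        tp = int(self.table.loc[cls_, cls_]) if cls_ in self.row_classes else 0
        return 100.0 * tp / total

    def accuracy(self) -> float | None:
        """100 * (diagonal over classes present in both axes) / all beats."""
        if self.grand_total == 0:
            return None
        shared = [c for c in self.row_classes if c in self.col_classes]
        correct = sum(int(self.table.loc[c, c]) for c in shared)
        return 100.0 * correct / self.grand_total


def sensitivity(cm: ConfusionMatrix, cls_: str) -> float | None:
    return cm.sensitivity(cls_)


def positive_predictive_value(cm: ConfusionMatrix, cls_: str) -> float | None:
    return cm.positive_predictive_value(cls_)


def accuracy(cm: ConfusionMatrix) -> float | None:
    return cm.accuracy()


def ave_from_rates(
    se_n: float | None,
    pp_n: float | None,
    se_v: float | None,
    pp_v: float | None,
) -> float | None:
    """Ave = (Se_N + PP_N + Se_V + PP_V) / 4 (percent); None if any term is."""
    terms = (se_n, pp_n, se_v, pp_v)
    if any(t is None for t in terms):
        return None
    return sum(terms) / 4.0


def compute_ave(cm: ConfusionMatrix) -> float | None:
    """The model-selection criterion: mean of Se and PP for classes N and V."""
    return ave_from_rates(
        cm.sensitivity("N"),
        cm.positive_predictive_value("N"),
        cm.sensitivity("V"),
        cm.positive_predictive_value("V"),
    )


def stage2_input_count(cm: ConfusionMatrix) -> int:
    """Beats entering the RR-ratio stage: total minus V-labelled beats."""
    remaining = cm.grand_total - cm.col_total("V")
    if remaining < 0:
        raise ValueError("V-labelled count exceeds total; inconsistent matrix")
    return remaining


def per_recording_report(
    reference: Iterable[str],
    algorithm: Iterable[str],
    record_ids: Iterable[str],
    known_records: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-recording Se/PP for N, S, V plus accuracy, and a pooled Total row.

    Accuracy per recording covers *all* its beats, including reference F and
    Q beats that the 3-class final system can never label correctly. The
    Total row is computed from the pooled confusion matrix, never by
    averaging per-recording rows. Undefined metrics are NaN.
    """
    ref = np.asarray(list(reference), dtype=object)
    alg = np.asarray(list(algorithm), dtype=object)
    rec = np.asarray([str(r) for r in record_ids], dtype=object)
    if not (len(ref) == len(alg) == len(rec)):
        raise ValueError("inputs are not aligned")
    if known_records is not None:
        unknown = set(rec) - set(str(r) for r in known_records)
        if unknown:
            raise ValueError(f"unknown record ids: {sorted(unknown)}")

    def _row(cm: ConfusionMatrix, label: str) -> dict:
        out = {
            "record": label,
            "n_N": cm.row_total("N"),
            "n_S": cm.row_total("S"),
            "n_V": cm.row_total("V"),
        }
        for cls_ in ("N", "S", "V"):
            se = cm.sensitivity(cls_)
            pp = cm.positive_predictive_value(cls_)
            out[f"Se_{cls_}"] = np.nan if se is None else se
            out[f"PP_{cls_}"] = np.nan if pp is None else pp
        acc = cm.accuracy()
        out["Acc"] = np.nan if acc is None else acc
        return out

    rows = []
    pooled: ConfusionMatrix | None = None
    for rid in sorted(set(rec)):
        mask = rec == rid
        cm = ConfusionMatrix.from_labels(ref[mask], alg[mask])
        rows.append(_row(cm, rid))
        pooled = cm if pooled is None else pooled + cm
    if pooled is None:
        raise ValueError("no beats to report")
    rows.append(_row(pooled, "Total"))
    return pd.DataFrame(rows)


def format_report(report: pd.DataFrame) -> pd.DataFrame:
    """Display form of a report: percentages rounded half-up, NaN as '-'."""
    out = report.copy()
    pct_cols = [c for c in out.columns if c.startswith(("Se_", "PP_")) or c == "Acc"]
    for c in pct_cols:
        out[c] = [
            "-" if v is None else f"{v:.1f}"
            for v in (round_half_up(v) for v in out[c])
        ]
    return out
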