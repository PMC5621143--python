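"""Accuracy assessment: contingency tables and the standard remote-sensing
metrics (overall, user's and producer's accuracy, omission and commission
errors).

Conventions
-----------
* Rows of the 2 x 2 table are actual classes, columns are predictions, in
  the order (target weed, other vegetation).
* overall   = 100 * trace / N
* producer's(c) = 100 * counts[c, c] / row_total(c);  omission(c) = 100 - producer's(c)
* user's(c)     = 100 * counts[c, c] / col_total(c)
* commission(c) = 100 * (col_total(c) - counts[c, c]) / row_total(other(c)) —
  foreign pixels wrongly assigned to c, as a share of the foreign class.
* A metric whose denominator is zero is reported as ``None`` (undefined),
  never as 0.
* Values are kept at full precision; rounding (half-up, 2 decimals) happens
  only at presentation.
"""

from __future__ import annotations

import dataclasses
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional

import numpy as np

from ocweed.errors import InputError
from ocweed.scene_sim import OTHER, TARGET

_CLASS_ORDER = (TARGET, OTHER)
_CLASS_NAMES = {TARGET: "S. marianum", OTHER: "Other vegetation"}


@dataclasses.dataclass
class ConfusionTable:
    """2 x 2 actual-vs-predicted pixel counts."""

    counts: np.ndarray  # rows actual, cols predicted, order (target, other)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2):
            raise InputError("confusion table must be 2 x 2")
        if (self.counts < 0).any():
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_total(self, code: int) -> int:
        return int(self.counts[_CLASS_ORDER.index(code)].sum())

    def col_total(self, code: int) -> int:
        return int(self.counts[:, _CLASS_ORDER.index(code)].sum())


def confusion(actual, predicted) -> ConfusionTable:
    """Tally actual vs predicted class codes (codes in {1, 2})."""
    actual = np.asarray(actual).ravel()
    predicted = np.asarray(predicted).ravel()
    if actual.shape != predicted.shape:
        raise InputError(
            f"length mismatch: {actual.size} actual vs {predicted.size} predicted"
        )
    for name, arr in (("actual", actual), ("predicted", predicted)):
        if arr.size and not np.isin(arr, _CLASS_ORDER).all():
            bad = sorted(set(np.unique(arr)) - set(_CLASS_ORDER))
            raise InputError(f"{name} codes contain illegal values {bad}")
    counts = np.empty((2, 2), dtype=np.int64)
    for i, a in enumerate(_CLASS_ORDER):
        for j, p in enumerate(_CLASS_ORDER):
            counts[i, j] = int(np.sum((actual == a) & (predicted == p)))
    return ConfusionTable(counts)


@dataclasses.dataclass
class MetricsReport:
    """Percent-scale accuracy metrics; per-class values keyed by class code."""

    overall_accuracy: Optional[float]
    users_accuracy: dict
    producers_accuracy: dict
    omission_error: dict
    commission_error: dict
    table: ConfusionTable = None

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "users_accuracy": dict(self.users_accuracy),
            "producers_accuracy": dict(self.producers_accuracy),
            "omission_error": dict(self.omission_error),
            "commission_error": dict(self.commission_error),
            "counts": None if self.table is None else self.table.counts.tolist(),
        }

    def rounded(self, ndigits: int = 2) -> "MetricsReport":
        return MetricsReport(
            overall_accuracy=round_half_up(self.overall_accuracy, ndigits),
            users_accuracy={c: round_half_up(v, ndigits)
                            for c, v in self.users_accuracy.items()},
            producers_accuracy={c: round_half_up(v, ndigits)
                                for c, v in self.producers_accuracy.items()},
            omission_error={c: round_half_up(v, ndigits)
                            for c, v in self.omission_error.items()},
            commission_error={c: round_half_up(v, ndigits)
                              for c, v in self.commission_error.items()},
            table=self.table,
        )

    def to_text(self, title: str = "") -> str:
        """Aligned contingency-table report in the journal layout."""
        r = self.rounded(2)
        c = self.table.counts if self.table is not None else np.zeros((2, 2), int)
        lines = []
        head = f"{title} (Overall accuracy {r.overall_accuracy}%)" if title else (
            f"Overall accuracy {r.overall_accuracy}%")
        lines.append(head)
        lines.append(f"{'Actual':<18}{'Target px':>10}{'Other px':>10}"
                     f"{'User acc %':>12}{'Prod acc %':>12}")
        for i, code in enumerate(_CLASS_ORDER):
            lines.append(
                f"{_CLASS_NAMES[code]:<18}{c[i, 0]:>10}{c[i, 1]:>10}"
                f"{str(r.users_accuracy[code]):>12}"
                f"{str(r.producers_accuracy[code]):>12}"
            )
        return "\n".join(lines)


def round_half_up(value: Optional[float], ndigits: int = 2) -> Optional[float]:
    """Display rounding: half-up, as tabulated accuracy figures usually are."""
    if value is None:
        return None
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else 100.0 * num / den


def metrics(table: ConfusionTable) -> MetricsReport:
    """All Table-style accuracy metrics from a confusion table."""
    c = table.counts
    n = table.total
    overall = _ratio(int(np.trace(c)), n)
    users, producers, omission, commission = {}, {}, {}, {}
    for i, code in enumerate(_CLASS_ORDER):
        other_i = 1 - i
        diag = int(c[i, i])
        producers[code] = _ratio(diag, int(c[i].sum()))
        users[code] = _ratio(diag, int(c[:, i].sum()))
        omission[code] = (None if producers[code] is None
                          else 100.0 - producers[code])
        commission[code] = _ratio(int(c[:, i].sum()) - diag, int(c[other_i].sum()))
    return MetricsReport(
        overall_accuracy=overall,
        users_accuracy=users,
        producers_accuracy=producers,
        omission_error=omission,
        commission_error=commission,
        table=table,
    )
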