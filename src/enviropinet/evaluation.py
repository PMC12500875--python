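"""Performance metrics and comparison-table assembly.

Two headline metrics are used throughout:

* the coefficient of determination
  ``R^2 = 1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar)^2``, and
* a bounded symmetric mean absolute percentage error
  ``sMAPE = (100/n) sum |y_i - Y_i| / (|y_i| + |Y_i|)`` — note the
  denominator is the plain sum of magnitudes (no factor of 2), so the
  value lies in [0, 100].

Pearson's r (with a two-sided p-value) is reported alongside but never
used for model selection.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "r_squared",
    "smape",
    "pearson_r",
    "aggregate_seeds",
    "EvaluationReport",
    "ComparisonTable",
    "comparison_table",
    "REDUCER_ORDER",
    "FAMILY_ORDER",
]

REDUCER_ORDER = ("BP", "PCA", "KPCA", "Autoencoder")
FAMILY_ORDER = ("NN", "LR", "GBR", "RFR", "SVR")
SPLIT_ORDER = ("train", "test")

#: Naming aliases accepted for the gradient-boosting family.
FAMILY_ALIASES = {"GFR": "GBR"}


def _pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if y.shape != p.shape:
        raise ValueError("observed/predicted length mismatch")
    return y, p


def r_squared(observed, predicted) -> float:
    """Coefficient of determination (may be negative; 1 is a perfect fit)."""
    y, p = _pair(observed, predicted)
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed values are constant; R^2 undefined")
    ss_res = float(np.sum((y - p) ** 2))
    return 1.0 - ss_res / ss_tot


def smape(observed, predicted) -> float:
    """Symmetric MAPE in percent, bounded by 100."""
    y, p = _pair(observed, predicted)
    denom = np.abs(y) + np.abs(p)
    zero = np.nonzero(denom == 0)[0]
    if zero.size:
        raise ValueError(f"|observed| + |predicted| is zero at row(s) {zero[:5].tolist()}")
    return float(100.0 / y.size * np.sum(np.abs(y - p) / denom))


def pearson_r(observed, predicted) -> tuple[float, float]:
    """Sample Pearson correlation and two-sided p-value."""
    y, p = _pair(observed, predicted)
    if y.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(y) == 0 or np.ptp(p) == 0:
        raise ValueError("constant vector; correlation undefined")
    res = stats.pearsonr(y, p)
    return float(res.statistic), float(res.pvalue)


def aggregate_seeds(values: Sequence[float]) -> tuple[float, float | None]:
    """Mean and population SD across seeds; SD omitted for a single seed."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("no values to aggregate")
    mean = float(v.mean())
    sd = float(v.std(ddof=0)) if v.size > 1 else None
    return mean, sd


@dataclass
class EvaluationReport:
    """Tidy per-(reducer, family, split) metric records.

    Each record carries ``reducer, family, split, metric, value, sd,
    n_seeds, n_rows`` — SD only for multi-seed (stochastic) models.
    """

    records: list[dict] = field(default_factory=list)

    def add(
        self,
        reducer: str,
        family: str,
        split: str,
        metric: str,
        value: float,
        sd: float | None = None,
        n_seeds: int = 1,
        n_rows: int | None = None,
    ) -> None:
        family = FAMILY_ALIASES.get(family, family)
        self.records.append(
            {
                "reducer": reducer,
                "family": family,
                "split": split,
                "metric": metric,
                "value": float(value),
                "sd": None if sd is None else float(sd),
                "n_seeds": int(n_seeds),
                "n_rows": n_rows,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


@dataclass
class ComparisonTable:
    """Reducer x regressor grids for each metric, train and test."""

    tidy: pd.DataFrame
    grids: dict[str, pd.DataFrame]  # metric -> rendered grid (strings)

    def to_csv(self, metric: str) -> str:
        return self.grids[metric].to_csv()

    def render_text(self) -> str:
        out = io.StringIO()
        for metric, grid in self.grids.items():
            out.write(f"== {metric} ==\n")
            out.write(grid.to_string())
            out.write("\n\n")
        return out.getvalue()


def _cell(value, sd) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "NA"
    txt = f"{value:.3g}"
    if sd is not None and not (isinstance(sd, float) and np.isnan(sd)):
        txt += f" ({sd:.2g})"
    return txt


def comparison_table(
    report: EvaluationReport,
    metrics: Iterable[str] = ("r2", "smape"),
) -> ComparisonTable:
    """Assemble the full comparison grid from a report.

    Every (reducer, family, split) cell of the canonical ordering is
    rendered; combinations absent from the report appear as ``NA`` rather
    than being dropped.  Output is deterministic, so re-rendering a saved
    report is byte-identical.
    """
    tidy = report.to_frame()
    grids: dict[str, pd.DataFrame] = {}
    lookup = {}
    if len(tidy):
        for rec in report.records:
            lookup[(rec["reducer"], rec["family"], rec["split"], rec["metric"])] = rec
    for metric in metrics:
        rows = []
        for reducer in REDUCER_ORDER:
            for family in FAMILY_ORDER:
                row = {"reducer": reducer, "family": family}
                for split in SPLIT_ORDER:
                    rec = lookup.get((reducer, family, split, metric))
                    row[split] = _cell(
                        rec["value"] if rec else None, rec["sd"] if rec else None
                    )
                rows.append(row)
        grids[metric] = pd.DataFrame(rows).set_index(["reducer", "family"])
    return ComparisonTable(tidy=tidy, grids=grids)
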