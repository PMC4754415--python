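"""Outlier screening with the generalized extreme studentized deviate test.

Rosner's gESD procedure tests for up to ``k`` outliers in an approximately
normal sample: at each step the value with the largest studentized absolute
deviation is removed and its statistic R_i compared with the critical value

    lambda_i = (n - i) * t_{p, n-i-1} / sqrt((n - i - 1 + t^2) (n - i + 1))

with ``t`` the p-quantile of Student's t on n-i-1 degrees of freedom and
``p = 1 - alpha / (2 (n - i + 1))``. The declared number of outliers is the
largest i with R_i > lambda_i.

Screening is applied per experimental condition (treatment x nucleus x gene
cell for expression; treatment for cortisol), at alpha = 0.05 with at most
20% of the cell's sample removable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class EsdResult:
    """Outcome of one gESD run.

    ``r_stats`` and ``lambda_crit`` have length equal to the configured
    maximum number of outliers (NaN-padded if iteration stopped early on a
    zero-variance remainder); ``outlier_indices`` are indices into the
    input vector in removal order, truncated to ``n_outliers``.
    """

    tested_values: np.ndarray
    r_stats: np.ndarray
    lambda_crit: np.ndarray
    n_outliers: int
    outlier_indices: np.ndarray

    def __post_init__(self) -> None:
        assert len(self.r_stats) == len(self.lambda_crit)
        assert self.n_outliers <= len(self.r_stats)


def _esd_critical(n: int, i: int, alpha: float) -> float:
    """Critical value lambda_i for the i-th (1-based) gESD step."""
    nu = n - i - 1
    p = 1.0 - alpha / (2.0 * (n - i + 1))
    t = stats.t.ppf(p, nu)
    return (n - i) * t / math.sqrt((nu + t * t) * (n - i + 1))


def gesd(
    values: Sequence[float], alpha: float = 0.05, max_outliers: int = 1
) -> EsdResult:
    """Two-sided generalized ESD test for up to ``max_outliers`` outliers."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    n = len(x)
    if n < 5:
        raise ValueError(f"gESD requires n >= 5, got {n}")
    if max_outliers < 1:
        raise ValueError("max_outliers must be >= 1")
    if max_outliers > n - 2:
        max_outliers = n - 2

    remaining = np.arange(n)
    r_stats = np.full(max_outliers, np.nan)
    lam = np.full(max_outliers, np.nan)
    removed: list[int] = []
    for i in range(1, max_outliers + 1):
        sub = x[remaining]
        sd = sub.std(ddof=1)
        if sd == 0.0:
            break
        dev = np.abs(sub - sub.mean())
        j = int(np.argmax(dev))
        r_stats[i - 1] = dev[j] / sd
        lam[i - 1] = _esd_critical(n, i, alpha)
        removed.append(int(remaining[j]))
        remaining = np.delete(remaining, j)

    n_out = 0
    for i in range(len(removed), 0, -1):
        if r_stats[i - 1] > lam[i - 1]:
            n_out = i
            break
    return EsdResult(
        tested_values=x,
        r_stats=r_stats,
        lambda_crit=lam,
        n_outliers=n_out,
        outlier_indices=np.asarray(removed[:n_out], dtype=int),
    )


def screen_dataset(
    table: pd.DataFrame,
    alpha: float = 0.05,
    max_frac: float = 0.2,
    value_col: str = "relative_expression",
    group_cols: Sequence[str] = ("treatment", "nucleus", "gene"),
    id_col: str = "fish_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen ``value_col`` per condition; returns (filtered, log).

    Per condition cell the maximum removable count is
    ``floor(max_frac * n_cell)``; cells with n < 5 (or a zero cap) are
    skipped and logged. The screening log records each removed row's value,
    R_i and lambda_i, plus one ``skipped`` row per untested cell.
    """
    group_cols = list(group_cols)
    keep = np.ones(len(table), dtype=bool)
    log_rows = []
    for key, grp in table.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n = len(grp)
        k = int(math.floor(max_frac * n))
        if n < 5 or k < 1:
            logger.info("screening skipped for %s (n=%d)", key, n)
            log_rows.append(key + ("", np.nan, np.nan, np.nan, 0, "skipped"))
            continue
        res = gesd(grp[value_col].to_numpy(), alpha=alpha, max_outliers=k)
        for order, idx in enumerate(res.outlier_indices, start=1):
            row = grp.iloc[int(idx)]
            keep[table.index.get_loc(row.name)] = False
            log_rows.append(
                key
                + (
                    str(row[id_col]) if id_col in grp.columns else str(row.name),
                    float(row[value_col]),
                    float(res.r_stats[order - 1]),
                    float(res.lambda_crit[order - 1]),
                    order,
                    "removed",
                )
            )
    log = pd.DataFrame(
        log_rows,
        columns=group_cols + [id_col, "value", "R", "lambda", "iteration", "status"],
    )
    return table.loc[keep].reset_index(drop=True), log
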