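"""Case-status assignment: codes, thresholded probability, bootstrap
imputation.

The three methods compared by the bias analysis. Threshold rules are
chosen on the predicted probability against true status (Youden's J or
closest-to-corner), with classification inclusive at the threshold.
Bootstrap imputation resamples the cohort, imputes status per record by
comparing a uniform draw with its predicted probability (strictly
below), and aggregates statistics over replicates as mean and
2.5th/97.5th percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bias import StatisticDefinition, battery_arrays, battery_values
from .errors import DegenerateInputError, SchemaError


def assign_by_code(table: pd.DataFrame, diversion: str) -> np.ndarray:
    """Status vector straight from the procedure-code flag."""
    col = f"code_{diversion}"
    if col not in table.columns:
        raise SchemaError(col)
    return np.asarray(table[col], dtype=bool)


@dataclass(frozen=True)
class ThresholdRule:
    diversion: str
    tau: float
    criterion: str  # "youden_j" | "closest_to_corner"
    sensitivity: float
    specificity: float
    flagged: bool = False

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def find_threshold(
    p_hat, truth, criterion: str = "youden_j", diversion: str = ""
) -> ThresholdRule:
    """Optimal classification threshold over the distinct predicted values.

    ``youden_j`` maximizes sensitivity + specificity - 1;
    ``closest_to_corner`` minimizes (1-sens)^2 + (1-spec)^2. Ties are
    broken toward the smallest threshold. A constant probability vector
    yields its single candidate, flagged.
    """
    if criterion not in ("youden_j", "closest_to_corner"):
        raise ValueError(f"unknown criterion {criterion!r}")
    p = np.asarray(p_hat, dtype=float)
    y = np.asarray(truth, dtype=bool)
    if p.shape != y.shape:
        raise ValueError("p_hat and truth must have equal length")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("truth must contain both classes")

    # thresholds descending: classify positive iff p >= tau
    order = np.argsort(-p, kind="stable")
    p_sorted = p[order]
    y_sorted = y[order]
    distinct = np.r_[np.diff(p_sorted) != 0, True]  # last index of each value
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(~y_sorted)[distinct]
    taus = p_sorted[distinct]
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    if criterion == "youden_j":
        score = -(sens + spec - 1.0)  # minimize
    else:
        score = (1.0 - sens) ** 2 + (1.0 - spec) ** 2
    # ties -> smallest threshold: taus are descending, so take the last argmin
    best = np.flatnonzero(score <= score.min() + 1e-15)[-1]
    flagged = taus.size == 1
    return ThresholdRule(
        diversion=diversion,
        tau=float(taus[best]),
        criterion=criterion,
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        flagged=flagged,
    )


def assign_by_threshold(p_hat, rule: ThresholdRule) -> np.ndarray:
    """Positive iff predicted probability >= rule.tau (inclusive)."""
    return np.asarray(p_hat, dtype=float) >= rule.tau


@dataclass(frozen=True)
class BIResult:
    statistic: str
    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_missing: int  # replicates where the statistic was inestimable


def impute_status(
    p_incontinent: np.ndarray,
    p_continent: np.ndarray,
    u: np.ndarray,
    u2: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Impute the two diversion statuses from predicted probabilities.

    Default (mutually exclusive): the unit interval is partitioned into
    [0, p_inc), [p_inc, p_inc + p_cont) and the remainder, so a single
    uniform assigns at most one type — mirroring the mutually exclusive
    true statuses. Passing a second uniform ``u2`` switches to
    independent per-type draws (u < p, strictly below).
    """
    if u2 is not None:
        return u < p_incontinent, u2 < p_continent
    s_inc = u < p_incontinent
    s_cont = ~s_inc & (u < p_incontinent + p_continent)
    return s_inc, s_cont


def bootstrap_impute(
    table: pd.DataFrame,
    p_hat: pd.DataFrame | np.ndarray,
    battery: list[StatisticDefinition],
    diversion: str,
    n_boot: int = 1000,
    seed=None,
    resample: bool = True,
    exclusive: bool = True,
    log: list[str] | None = None,
) -> list[BIResult]:
    """Bootstrap-imputation estimates of every statistic in the battery.

    Per replicate: resample rows with replacement to the original size
    (identity resampling when ``resample=False`` — a test hook), impute
    both diversion statuses from the predicted probabilities, and
    compute the battery for the requested ``diversion``. Point estimate
    is the replicate mean; the CI is the 2.5th/97.5th percentile.
    Inestimable replicate values are dropped from aggregation and
    counted.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if diversion not in ("incontinent", "continent"):
        raise ValueError(f"unknown diversion {diversion!r}")
    p = np.asarray(p_hat, dtype=float)
    if isinstance(p_hat, pd.DataFrame):
        p = np.column_stack(
            [np.asarray(p_hat["p_incontinent"]), np.asarray(p_hat["p_continent"])]
        )
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("p_hat must have two probability columns")
    n = len(table)
    if p.shape[0] != n:
        raise ValueError("p_hat rows must align with the table")

    rng = np.random.default_rng(seed)
    arrays = battery_arrays(table, battery)
    values = np.empty((n_boot, len(battery)))
    for b in range(n_boot):
        idx = rng.integers(0, n, n) if resample else np.arange(n)
        u = rng.random(n)
        u2 = None if exclusive else rng.random(n)
        s_inc, s_cont = impute_status(p[idx, 0], p[idx, 1], u, u2)
        status = s_inc if diversion == "incontinent" else s_cont
        values[b] = battery_values(arrays, status, idx)

    results = []
    for j, stat in enumerate(battery):
        col = values[:, j]
        ok = np.isfinite(col)
        n_missing = int((~ok).sum())
        if n_missing and log is not None:
            log.append(f"BI {diversion}/{stat.name}: {n_missing} inestimable replicates dropped")
        if ok.sum() == 0:
            results.append(BIResult(stat.name, np.nan, np.nan, np.nan, n_boot, n_missing))
            continue
        vals = col[ok]
        results.append(
            BIResult(
                statistic=stat.name,
                point=float(vals.mean()),
                ci_low=float(np.percentile(vals, 2.5)),
                ci_high=float(np.percentile(vals, 97.5)),
                n_boot=n_boot,
                n_missing=n_missing,
            )
        )
    return results
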