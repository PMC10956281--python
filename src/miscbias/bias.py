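"""Association statistics, standardized mean squared error (SMSE), and
the between-method bias comparison.

For a given status vector the battery measures: prevalence; the
association of status with continuous covariables as the slope of a
linear regression of the covariable on the status indicator (a
difference in means); and the association with binary covariables as
the log odds ratio from a logistic regression of the covariable on the
status indicator (identical to the 2x2 cross-product log-OR, with a
Haldane–Anscombe +0.5 correction when any cell is empty).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import COMORBIDITY_COLUMNS
from .errors import DegenerateInputError, SchemaError

STAT_KINDS = ("prevalence", "continuous_assoc", "binary_assoc")


@dataclass(frozen=True)
class StatisticDefinition:
    name: str
    kind: str
    column: str | None = None

    def __post_init__(self):
        if self.kind not in STAT_KINDS:
            raise ValueError(f"unknown statistic kind {self.kind!r}")
        if self.kind != "prevalence" and self.column is None:
            raise ValueError(f"{self.kind} statistic requires a column")


#: 30 statistics: prevalence, 3 continuous, 26 binary.
def default_battery() -> list[StatisticDefinition]:
    battery = [StatisticDefinition("prevalence", "prevalence")]
    for col in ("age", "operative_time", "acute_los"):
        battery.append(StatisticDefinition(col, "continuous_assoc", col))
    binary = (
        "sex_male",
        "elective",
        "general_anesthetic",
        "transfusion",
        "discharge_home_no_supports",
        "death_or_readmit_28d",
    ) + COMORBIDITY_COLUMNS[:20]
    for col in binary:
        battery.append(StatisticDefinition(col, "binary_assoc", col))
    assert len(battery) == 30
    return battery


# ---------------------------------------------------------------------------
# vectorized battery core (shared with bootstrap imputation)
# ---------------------------------------------------------------------------


def battery_arrays(table: pd.DataFrame, battery: list[StatisticDefinition]) -> dict:
    """Pre-extract covariable arrays for repeated battery evaluation."""
    layout: list[tuple[str, int | None]] = []
    bin_cols: list[np.ndarray] = []
    cont_cols: list[np.ndarray] = []
    for d in battery:
        if d.kind == "prevalence":
            layout.append(("prevalence", None))
            continue
        if d.column not in table.columns:
            raise SchemaError(d.column)
        if d.kind == "continuous_assoc":
            layout.append(("continuous", len(cont_cols)))
            cont_cols.append(np.asarray(table[d.column], dtype=float))
        else:
            layout.append(("binary", len(bin_cols)))
            bin_cols.append(np.asarray(table[d.column], dtype=bool))
    n = len(table)
    return {
        "layout": layout,
        "binary": np.column_stack(bin_cols) if bin_cols else np.empty((n, 0), dtype=bool),
        "continuous": np.column_stack(cont_cols) if cont_cols else np.empty((n, 0)),
    }


def battery_values(arrays: dict, status: np.ndarray, idx: np.ndarray | None = None) -> np.ndarray:
    """Evaluate the battery for one status vector; inestimable
    associations (single-class status) come back NaN."""
    status = np.asarray(status, dtype=bool)
    Xb = arrays["binary"] if idx is None else arrays["binary"][idx]
    Xc = arrays["continuous"] if idx is None else arrays["continuous"][idx]
    n = status.size
    n1 = int(status.sum())
    n0 = n - n1
    out = np.empty(len(arrays["layout"]))

    if Xb.shape[1]:
        if 0 < n1 < n:
            a = Xb[status].sum(axis=0).astype(float)
            c = Xb[~status].sum(axis=0).astype(float)
            b = n1 - a
            d = n0 - c
            zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
            a, b, c, d = (v + 0.5 * zero for v in (a, b, c, d))
            log_or = np.log(a * d / (b * c))
        else:
            log_or = np.full(Xb.shape[1], np.nan)
    else:
        log_or = np.empty(0)

    if Xc.shape[1]:
        if 0 < n1 < n:
            mean_diff = Xc[status].mean(axis=0) - Xc[~status].mean(axis=0)
        else:
            mean_diff = np.full(Xc.shape[1], np.nan)
    else:
        mean_diff = np.empty(0)

    for j, (kind, pos) in enumerate(arrays["layout"]):
        if kind == "prevalence":
            out[j] = n1 / n
        elif kind == "continuous":
            out[j] = mean_diff[pos]
        else:
            out[j] = log_or[pos]
    return out


# ---------------------------------------------------------------------------
# point estimates with standard errors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StatisticEstimate:
    statistic: str
    kind: str
    beta: float
    se: float
    method: str = ""
    corrected: bool = False  # Haldane-corrected 2x2 cells
    inestimable: bool = False


def compute_statistics(
    table: pd.DataFrame,
    status,
    battery: list[StatisticDefinition],
    method: str = "",
) -> list[StatisticEstimate]:
    """Battery point estimates with standard errors for one status vector."""
    if not battery:
        raise ValueError("battery must be non-empty")
    status = np.asarray(status, dtype=bool)
    if status.size != len(table):
        raise ValueError("status must align with the table")
    n = status.size
    n1 = int(status.sum())
    n0 = n - n1
    degenerate = n1 == 0 or n0 == 0

    out = []
    for d in battery:
        if d.kind == "prevalence":
            p = n1 / n
            se = math.sqrt(p * (1.0 - p) / n)
            out.append(StatisticEstimate(d.name, d.kind, p, se, method))
            continue
        if d.column not in table.columns:
            raise SchemaError(d.column)
        if degenerate:
            out.append(
                StatisticEstimate(d.name, d.kind, math.nan, math.nan, method, inestimable=True)
            )
            continue
        x = np.asarray(table[d.column], dtype=float)
        if d.kind == "continuous_assoc":
            x1, x0 = x[status], x[~status]
            beta = float(x1.mean() - x0.mean())
            ss = float(((x1 - x1.mean()) ** 2).sum() + ((x0 - x0.mean()) ** 2).sum())
            se = math.sqrt(ss / (n - 2) * (1.0 / n1 + 1.0 / n0)) if n > 2 else math.nan
            out.append(StatisticEstimate(d.name, d.kind, beta, se, method))
        else:
            xb = x > 0.5
            a = float((status & xb).sum())
            c = float((~status & xb).sum())
            b, dd = n1 - a, n0 - c
            corrected = min(a, b, c, dd) == 0
            if corrected:
                a, b, c, dd = a + 0.5, b + 0.5, c + 0.5, dd + 0.5
            beta = math.log(a * dd / (b * c))
            se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / dd)
            out.append(StatisticEstimate(d.name, d.kind, beta, se, method, corrected=corrected))
    return out


# ---------------------------------------------------------------------------
# SMSE and the method comparison
# ---------------------------------------------------------------------------

BETA_TRUE_TOL = 1e-12


def smse(beta: float, beta_true: float, mode: str = "analysis") -> float:
    """Standardized mean squared error of an estimate against the truth.

    ``literal`` mode divides the squared error by the (signed) true
    value; ``analysis`` mode (default) divides by its absolute value so
    the downstream log transform is defined for negative truths.
    """
    if mode not in ("analysis", "literal"):
        raise ValueError(f"unknown SMSE mode {mode!r}")
    if abs(beta_true) < BETA_TRUE_TOL:
        raise DegenerateInputError("beta_true is (numerically) zero; statistic excluded")
    denom = abs(beta_true) if mode == "analysis" else beta_true
    return (beta - beta_true) ** 2 / denom


@dataclass(frozen=True)
class SMSERecord:
    statistic: str
    method: str
    beta: float
    beta_true: float
    smse: float
    mode: str
    excluded: bool = False
    reason: str = ""


def smse_records(
    truth: list[StatisticEstimate],
    by_method: dict[str, list[StatisticEstimate]],
    mode: str = "analysis",
    log: list[str] | None = None,
) -> list[SMSERecord]:
    """SMSE of every (statistic, method) pair against the true estimates.

    Statistics with a zero or inestimable truth, or an inestimable
    method value, are emitted as excluded records with a reason."""
    truth_by_name = {t.statistic: t for t in truth}
    records = []
    for method, estimates in by_method.items():
        for est in estimates:
            bt = truth_by_name[est.statistic].beta
            if not math.isfinite(bt):
                rec = SMSERecord(est.statistic, method, est.beta, bt, math.nan, mode, True, "truth_inestimable")
            elif not math.isfinite(est.beta):
                rec = SMSERecord(est.statistic, method, est.beta, bt, math.nan, mode, True, "estimate_inestimable")
            elif abs(bt) < BETA_TRUE_TOL:
                rec = SMSERecord(est.statistic, method, est.beta, bt, math.nan, mode, True, "truth_zero")
            else:
                rec = SMSERecord(est.statistic, method, est.beta, bt, smse(est.beta, bt, mode), mode)
            if rec.excluded and log is not None:
                log.append(f"SMSE excluded: {method}/{est.statistic} ({rec.reason})")
            records.append(rec)
    return records


@dataclass
class MethodComparison:
    methods: list[str]
    median: dict[str, float]
    iqr: dict[str, tuple[float, float]]
    f_stat: float
    p_value: float
    tukey_p: dict[str, float]  # "methodA|methodB" -> p-value
    n_per_method: dict[str, int]
    n_excluded: int
    alpha: float = 0.05

    def separated(self, method: str) -> bool:
        """True when ``method`` differs from every other method at alpha."""
        return all(
            p < self.alpha
            for pair, p in self.tukey_p.items()
            if method in pair.split("|")
        )

    def to_dict(self) -> dict:
        return {
            "methods": self.methods,
            "median_smse": self.median,
            "iqr_smse": {k: list(v) for k, v in self.iqr.items()},
            "anova_f": self.f_stat,
            "anova_p": self.p_value,
            "tukey_p": self.tukey_p,
            "n_per_method": self.n_per_method,
            "n_excluded": self.n_excluded,
            "alpha": self.alpha,
        }


def compare_methods(
    records: list[SMSERecord], alpha: float = 0.05, log: list[str] | None = None
) -> MethodComparison:
    """One-way ANOVA of log(SMSE) with method as the factor, plus Tukey's
    studentized-range pairwise tests and per-method median/IQR.

    Zero or excluded SMSE values are dropped (log undefined), counted."""
    methods = sorted({r.method for r in records})
    if len(methods) < 2:
        raise DegenerateInputError("need >= 2 methods to compare")
    groups: dict[str, np.ndarray] = {}
    n_excluded = 0
    for m in methods:
        vals = np.array(
            [r.smse for r in records if r.method == m and not r.excluded and r.smse > 0]
        )
        n_excluded += sum(1 for r in records if r.method == m) - vals.size
        if vals.size < 2:
            raise DegenerateInputError(f"method {m!r} has < 2 usable SMSE values")
        groups[m] = vals
    if n_excluded and log is not None:
        log.append(f"method comparison: {n_excluded} zero/excluded SMSE values dropped")
    logs = [np.log(groups[m]) for m in methods]
    f_stat, p_value = sps.f_oneway(*logs)
    tukey = sps.tukey_hsd(*logs)
    tukey_p = {
        f"{methods[i]}|{methods[j]}": float(tukey.pvalue[i, j])
        for i in range(len(methods))
        for j in range(i + 1, len(methods))
    }
    return MethodComparison(
        methods=methods,
        median={m: float(np.median(groups[m])) for m in methods},
        iqr={
            m: (float(np.percentile(groups[m], 25)), float(np.percentile(groups[m], 75)))
            for m in methods
        },
        f_stat=float(f_stat),
        p_value=float(p_value),
        tukey_p=tukey_p,
        n_per_method={m: int(groups[m].size) for m in methods},
        n_excluded=n_excluded,
        alpha=alpha,
    )
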