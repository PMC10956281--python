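"""Multinomial prediction model: construction and internal validation.

The model is a single multinomial (generalized-logit) regression of the
3-level true status on selected covariates, with the no-procedure class
as reference. Construction follows a ranked single-pass forward
selection with likelihood-ratio retention, a degrees-of-freedom budget,
and best single fractional-polynomial (FP1) transformation of continuous
candidates. Internal validation is the bootstrap optimism correction of
the one-vs-rest c-statistic and the integrated calibration index (ICI).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.nonparametric.smoothers_lowess import lowess

from .cohort import CLASSES
from .errors import DegenerateInputError, SchemaError

OUTCOMES = ("incontinent", "continent")  # modelled vs. reference "none"
FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


# ---------------------------------------------------------------------------
# degrees-of-freedom budget
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DfBudget:
    """Permitted model degrees of freedom under four sample-size criteria
    (events-per-parameter, individual-prediction precision, global
    shrinkage, optimism in apparent fit); the budget is their minimum."""

    epv_df: float
    precision_df: float
    shrinkage_df: float
    optimism_df: float
    assumptions: dict = field(default_factory=dict)

    @property
    def allowed_df(self) -> float:
        return min(self.epv_df, self.precision_df, self.shrinkage_df, self.optimism_df)


def compute_df_budget(
    n: int,
    events: int,
    epv: float = 10.0,
    margin: float = 0.0005,
    shrinkage: float = 0.999,
    optimism: float = 0.0005,
    r2_anticipated: float = 0.072,
) -> DfBudget:
    """Degrees of freedom permitted for one outcome equation.

    * ``epv_df``: events / ``epv``.
    * ``precision_df``: largest p with expected mean absolute prediction
      error <= ``margin``, via the binary-outcome approximation
      MAPE = exp(-0.508 + 0.259 ln(phi) + 0.504 ln(p) - 0.544 ln(n)).
    * ``shrinkage_df``: largest p with expected uniform shrinkage
      >= ``shrinkage`` given an anticipated Cox-Snell R^2:
      p = n (S - 1) ln(1 - R^2 / S).
    * ``optimism_df``: same closed form with the shrinkage level implied
      by a targeted optimism ``delta`` in apparent fit:
      S' = R^2 / (R^2 + delta).

    The anticipated R^2 is an assumption (default 0.072) recorded in
    ``assumptions``; with the defaults the binding criterion is EPV.
    """
    if events <= 0:
        raise DegenerateInputError("events must be > 0")
    if not n > events:
        raise DegenerateInputError("n must exceed events")
    phi = events / n
    epv_df = events / epv
    ln_p = (
        math.log(margin) + 0.508 - 0.259 * math.log(phi) + 0.544 * math.log(n)
    ) / 0.504
    precision_df = math.exp(ln_p)
    r2 = r2_anticipated
    shrinkage_df = n * (shrinkage - 1.0) * math.log(1.0 - r2 / shrinkage)
    s_opt = r2 / (r2 + optimism)
    optimism_df = n * (s_opt - 1.0) * math.log(1.0 - r2 / s_opt)
    return DfBudget(
        epv_df=epv_df,
        precision_df=precision_df,
        shrinkage_df=shrinkage_df,
        optimism_df=optimism_df,
        assumptions={
            "prevalence": phi,
            "epv": epv,
            "mape_margin": margin,
            "shrinkage_target": shrinkage,
            "optimism_target": optimism,
            "r2_anticipated": r2,
        },
    )


# ---------------------------------------------------------------------------
# multinomial logit core
# ---------------------------------------------------------------------------


@dataclass
class _CoreFit:
    intercepts: np.ndarray  # (2,)
    coef: np.ndarray  # (k, 2) on the raw covariate scale
    loglik: float
    converged: bool
    separated: bool = False  # quasi-separation (runaway standardized coefficient)


def status_codes(status) -> np.ndarray:
    """Encode true status as 0 = none, 1 = incontinent, 2 = continent."""
    s = np.asarray(pd.Series(status).astype(str))
    codes = np.full(s.shape, -1, dtype=np.int64)
    codes[s == "none"] = 0
    codes[s == "incontinent"] = 1
    codes[s == "continent"] = 2
    if (codes < 0).any():
        bad = sorted(set(s) - set(CLASSES))
        raise ValueError(f"unknown status values: {bad}")
    return codes


def _fit_core(
    X: np.ndarray,
    codes: np.ndarray,
    weights: np.ndarray | None = None,
    ridge: float = 0.0,
    max_iter: int = 300,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
) -> _CoreFit:
    """Maximum-likelihood multinomial logit (reference class 0) via
    L-BFGS on the standardized design; coefficients are returned on the
    raw scale. ``ridge`` adds 0.5*ridge*sum(beta^2) on standardized
    non-intercept coefficients (guarded estimation under separation)."""
    n, k = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    Y = np.zeros((n, 2))
    Y[codes == 1, 0] = 1.0
    Y[codes == 2, 1] = 1.0

    if k:
        mean = (w @ X) / wsum
        var = (w @ (X - mean) ** 2) / wsum
        sd = np.sqrt(var)
        sd[sd == 0] = 1.0
        Z = (X - mean) / sd
    else:
        Z = X

    theta0 = np.zeros((k + 1, 2))
    if warm is not None:
        # warm start given on the raw covariate scale
        w_int, w_coef = warm
        if k:
            theta0[1:] = w_coef * sd[:, None]
            theta0[0] = w_int + mean @ w_coef
        else:
            theta0[0] = w_int
    else:
        n1 = max(w[codes == 1].sum(), 0.5)
        n2 = max(w[codes == 2].sum(), 0.5)
        n0 = max(w[codes == 0].sum(), 0.5)
        theta0[0] = [math.log(n1 / n0), math.log(n2 / n0)]

    Z1 = np.column_stack([np.ones(n), Z])  # (n, k+1)

    def nll_grad_p(theta):
        eta = Z1 @ theta  # (n, 2)
        m = np.maximum(np.max(eta, axis=1), 0.0)
        lse = m + np.log(np.exp(-m) + np.exp(eta[:, 0] - m) + np.exp(eta[:, 1] - m))
        ll = float(np.sum(w * (np.sum(Y * eta, axis=1) - lse)))
        P = np.exp(eta - lse[:, None])
        grad = Z1.T @ (w[:, None] * (P - Y))
        pen = 0.0
        if ridge > 0 and k:
            pen = 0.5 * ridge * float(np.sum(theta[1:] ** 2))
            grad = grad.copy()
            grad[1:] += ridge * theta[1:]
        return (-ll + pen), grad, P

    # damped Newton (IRLS): the (2(k+1))^2 Hessian is cheap at this width
    theta = theta0
    f_cur, grad, P = nll_grad_p(theta)
    converged = False
    for _ in range(max_iter):
        W1 = w * P[:, 0] * (1.0 - P[:, 0])
        W2 = w * P[:, 1] * (1.0 - P[:, 1])
        W12 = -w * P[:, 0] * P[:, 1]
        H11 = Z1.T @ (W1[:, None] * Z1)
        H22 = Z1.T @ (W2[:, None] * Z1)
        H12 = Z1.T @ (W12[:, None] * Z1)
        H = np.block([[H11, H12], [H12, H22]])
        if ridge > 0 and k:
            pen_diag = np.r_[0.0, np.full(k, ridge), 0.0, np.full(k, ridge)]
            H[np.diag_indices_from(H)] += pen_diag
        g = grad.T.ravel()  # (2(k+1),) ordered [outcome1 params, outcome2 params]
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(H.shape[0]), g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        direction = -step.reshape(2, k + 1).T
        # backtracking line search on the penalized objective
        t = 1.0
        for _ in range(30):
            f_new, grad_new, P_new = nll_grad_p(theta + t * direction)
            if f_new <= f_cur - 1e-4 * t * float(g @ step):
                break
            t *= 0.5
        if f_new > f_cur:  # no improvement at all: stop at current point
            break
        improved = f_cur - f_new
        theta = theta + t * direction
        f_cur, grad, P = f_new, grad_new, P_new
        if improved < 1e-9 * (1.0 + abs(f_cur)) or np.max(np.abs(grad)) < 1e-6:
            converged = True
            break

    if k:
        coef = theta[1:] / sd[:, None]
        intercepts = theta[0] - mean @ coef
    else:
        coef = np.zeros((0, 2))
        intercepts = theta[0]
    # report the unpenalized log-likelihood at the solution
    ll = -f_cur
    if ridge > 0 and k:
        ll += 0.5 * ridge * float(np.sum(theta[1:] ** 2))
    separated = bool(k and np.max(np.abs(theta[1:])) > _SEPARATION_COEF)
    return _CoreFit(
        intercepts=intercepts,
        coef=coef,
        loglik=float(ll),
        converged=converged,
        separated=separated,
    )


# ---------------------------------------------------------------------------
# terms and fractional polynomials
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CandidateVariable:
    name: str
    rank: int
    kind: str  # "binary" | "continuous"

    def __post_init__(self):
        if self.kind not in ("binary", "continuous"):
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.rank < 1:
            raise ValueError("rank must be a positive integer")


@dataclass(frozen=True)
class Term:
    """One model column: a covariate plus, for continuous covariates, its
    FP1 power and positivity shift."""

    name: str
    kind: str
    power: float = 1.0
    shift: float = 0.0
    flagged: bool = False


def fp_shift(x: np.ndarray) -> float:
    """Shift making the covariate strictly positive: 0 when already
    positive, else the smallest positive spacing of distinct values
    above the minimum (1 when there is no spacing)."""
    uniq = np.unique(x[np.isfinite(x)])
    if uniq.size == 0:
        return 1.0
    if uniq[0] > 0:
        return 0.0
    spacing = 1.0 if uniq.size < 2 else float(np.min(np.diff(uniq)))
    return spacing - float(uniq[0])


def fp_transform(x: np.ndarray, power: float, shift: float) -> np.ndarray:
    t = np.asarray(x, dtype=float) + shift
    if power == 0.0:
        return np.log(t)
    return t**power


def term_column(term: Term, table: pd.DataFrame) -> np.ndarray:
    if term.name not in table.columns:
        raise SchemaError(term.name)
    x = np.asarray(table[term.name], dtype=float)
    if term.kind == "continuous":
        return fp_transform(x, term.power, term.shift)
    return x


def build_design(terms: list[Term], table: pd.DataFrame) -> np.ndarray:
    if not terms:
        return np.empty((len(table), 0))
    return np.column_stack([term_column(t, table) for t in terms])


def select_fp1(
    x: np.ndarray,
    codes: np.ndarray,
    base_X: np.ndarray | None = None,
    powers=FP_POWERS,
    ridge: float = 0.0,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[float, float, bool]:
    """Best single fractional-polynomial power for a continuous covariate.

    Fits the multinomial model with the transformed covariate appended to
    ``base_X`` for every power in ``powers`` and returns the power with
    the smallest deviance (ties broken toward the identity, p = 1).
    Constant covariates return (1.0, 0.0, flagged=True).
    """
    x = np.asarray(x, dtype=float)
    if np.unique(x).size <= 1:
        return 1.0, 0.0, True
    shift = fp_shift(x)
    base = np.empty((x.size, 0)) if base_X is None else base_X
    warm_p = None
    if warm is not None:
        warm_p = (warm[0], np.vstack([warm[1], np.zeros((1, 2))]))
    deviances = {}
    for p in powers:
        Xp = np.column_stack([base, fp_transform(x, p, shift)])
        deviances[p] = -2.0 * _fit_core(Xp, codes, ridge=ridge, warm=warm_p).loglik
    best = min(deviances, key=lambda p: (deviances[p], abs(p - 1.0)))
    if 1.0 in deviances and deviances[1.0] <= deviances[best] + 1e-8:
        best = 1.0
    return float(best), shift, False


# ---------------------------------------------------------------------------
# fitted model
# ---------------------------------------------------------------------------

_SEPARATION_COEF = 30.0  # |standardized coef| beyond this flags quasi-separation


@dataclass
class FittedModel:
    """Multinomial model over {none, incontinent, continent} with ``none``
    as reference: per-outcome intercept and one coefficient per term."""

    terms: list[Term]
    intercepts: np.ndarray  # (2,) for (incontinent, continent)
    coef: np.ndarray  # (n_terms, 2)
    loglik: float
    trace: list[dict] = field(default_factory=list)
    allowed_df: float = math.inf
    alpha: float = 0.05
    ridge: float = 0.0

    @property
    def df_per_outcome(self) -> int:
        return len(self.terms)

    def to_dict(self) -> dict:
        return {
            "classes": list(CLASSES),
            "reference": "none",
            "outcomes": list(OUTCOMES),
            "terms": [
                {
                    "name": t.name,
                    "kind": t.kind,
                    "power": t.power,
                    "shift": t.shift,
                    "flagged": t.flagged,
                }
                for t in self.terms
            ],
            "intercepts": list(map(float, self.intercepts)),
            "coef": [list(map(float, row)) for row in self.coef],
            "loglik": self.loglik,
            "trace": self.trace,
            "allowed_df": self.allowed_df if math.isfinite(self.allowed_df) else None,
            "alpha": self.alpha,
            "ridge": self.ridge,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        return cls(
            terms=[Term(**t) for t in d["terms"]],
            intercepts=np.asarray(d["intercepts"], dtype=float),
            coef=np.asarray(d["coef"], dtype=float).reshape(len(d["terms"]), 2),
            loglik=float(d["loglik"]),
            trace=list(d.get("trace", [])),
            allowed_df=d["allowed_df"] if d.get("allowed_df") is not None else math.inf,
            alpha=float(d.get("alpha", 0.05)),
            ridge=float(d.get("ridge", 0.0)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "FittedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _probabilities(intercepts, coef, X) -> np.ndarray:
    if X.shape[1]:
        eta = X @ coef + intercepts
    else:
        eta = np.tile(np.asarray(intercepts, dtype=float), (X.shape[0], 1))
    m = np.maximum(np.max(eta, axis=1), 0.0)
    lse = m + np.log(np.exp(-m) + np.exp(eta[:, 0] - m) + np.exp(eta[:, 1] - m))
    p = np.empty((X.shape[0], 3))
    p[:, 0] = np.exp(-lse)
    p[:, 1] = np.exp(eta[:, 0] - lse)
    p[:, 2] = np.exp(eta[:, 1] - lse)
    return p


def predict_probabilities(model: FittedModel, table: pd.DataFrame) -> pd.DataFrame:
    """Per-record probability triplet (columns p_none / p_incontinent /
    p_continent); rows sum to 1."""
    X = build_design(model.terms, table)
    p = _probabilities(model.intercepts, model.coef, X)
    return pd.DataFrame(p, columns=["p_none", "p_incontinent", "p_continent"], index=table.index)


def forward_select(
    candidates: list[CandidateVariable],
    table: pd.DataFrame,
    alpha: float = 0.05,
    budget: DfBudget | None = None,
    ridge: float = 0.0,
    fp_powers=FP_POWERS,
) -> FittedModel:
    """Single-pass forward selection in rank order.

    Every candidate is offered once; a candidate enters both outcome
    equations simultaneously and is retained iff the likelihood-ratio
    test of its addition has p <= ``alpha`` (2 df: one coefficient per
    outcome equation) and the per-outcome df budget is not exceeded.
    Continuous candidates are offered as their best FP1 transformation
    given the terms already retained. The returned trace records every
    offer (kept or dropped, with the LRT and any separation flag).
    """
    ranks = [c.rank for c in candidates]
    if len(set(ranks)) != len(ranks):
        raise ValueError("candidate ranks must be unique")
    for c in candidates:
        if c.name not in table.columns:
            raise SchemaError(c.name)

    codes = status_codes(table["true_status"])
    allowed = budget.allowed_df if budget is not None else math.inf

    terms: list[Term] = []
    X = np.empty((len(table), 0))
    current = _fit_core(X, codes, ridge=ridge)
    trace: list[dict] = []

    for cand in sorted(candidates, key=lambda c: c.rank):
        x = np.asarray(table[cand.name], dtype=float)
        warm = (current.intercepts, np.vstack([current.coef, np.zeros((1, 2))]))
        if cand.kind == "continuous":
            power, shift, flat = select_fp1(
                x, codes, X, powers=fp_powers, ridge=ridge,
                warm=(current.intercepts, current.coef),
            )
            term = Term(cand.name, "continuous", power=power, shift=shift, flagged=flat)
        else:
            term = Term(cand.name, "binary")
        col = term_column(term, table)
        if np.unique(col).size <= 1:
            trace.append(
                {"variable": cand.name, "rank": cand.rank, "kept": False,
                 "reason": "constant", "lrt": 0.0, "p_value": 1.0}
            )
            continue
        X_try = np.column_stack([X, col])
        fit_try = _fit_core(X_try, codes, ridge=ridge, warm=warm)
        lrt = max(0.0, 2.0 * (fit_try.loglik - current.loglik))
        p_value = float(stats.chi2.sf(lrt, df=2))
        separated = fit_try.separated or not fit_try.converged
        row = {
            "variable": cand.name,
            "rank": cand.rank,
            "kind": cand.kind,
            "power": term.power if cand.kind == "continuous" else None,
            "shift": term.shift if cand.kind == "continuous" else None,
            "lrt": lrt,
            "p_value": p_value,
            "separation_flag": separated,
        }
        if p_value > alpha:
            row.update(kept=False, reason="lrt_not_significant")
        elif len(terms) + 1 > allowed:
            row.update(kept=False, reason="df_budget")
        else:
            row.update(kept=True, reason="retained")
            terms.append(term)
            X = X_try
            current = fit_try
        trace.append(row)

    return FittedModel(
        terms=terms,
        intercepts=current.intercepts,
        coef=current.coef,
        loglik=current.loglik,
        trace=trace,
        allowed_df=allowed,
        alpha=alpha,
        ridge=ridge,
    )


def refit_coefficients(
    model: FittedModel, X: np.ndarray, codes: np.ndarray, ridge: float | None = None
) -> _CoreFit:
    """Re-estimate coefficients with the model structure held fixed,
    warm-started at the model's current coefficients."""
    return _fit_core(
        X,
        codes,
        ridge=model.ridge if ridge is None else ridge,
        warm=(model.intercepts, model.coef),
    )


# ---------------------------------------------------------------------------
# discrimination / calibration / internal validation
# ---------------------------------------------------------------------------


def c_statistic(p: np.ndarray, y: np.ndarray) -> float:
    """One-vs-rest concordance (area under the ROC curve)."""
    y = np.asarray(y, dtype=bool)
    if y.all() or not y.any():
        raise DegenerateInputError("c-statistic needs both classes present")
    return float(roc_auc_score(y, np.asarray(p, dtype=float)))


def _loess_observed(p: np.ndarray, y: np.ndarray, frac: float) -> np.ndarray:
    delta = 0.001 * (float(p.max()) - float(p.min())) if p.size > 1000 else 0.0
    y = np.asarray(y, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = lowess(y, p, frac=frac, it=0, delta=delta, return_sorted=False)
    bad = ~np.isfinite(sm)
    if bad.any():  # degenerate windows (ties/extreme clustering): interpolate
        ok = ~bad
        if ok.any():
            order = np.argsort(p[ok], kind="stable")
            sm[bad] = np.interp(p[bad], p[ok][order], sm[ok][order])
        else:
            sm[:] = y.mean()
    return np.clip(sm, 0.0, 1.0)


def integrated_calibration_index(p: np.ndarray, y: np.ndarray, frac: float = 0.75) -> float:
    """Mean absolute difference between predicted probabilities and the
    LOESS-smoothed observed event rate."""
    p = np.asarray(p, dtype=float)
    return float(np.mean(np.abs(p - _loess_observed(p, y, frac))))


@dataclass
class OutcomeValidation:
    c_apparent: float
    c_corrected: float
    c_ci: tuple[float, float]
    ici_apparent: float
    ici_corrected: float
    ici_ci: tuple[float, float]
    calibration_curve: list[tuple[float, float]]


@dataclass
class ValidationReport:
    per_outcome: dict[str, OutcomeValidation]
    n_boot: int
    n_redraws: int
    seed_entropy: str

    def to_dict(self) -> dict:
        return {
            "n_boot": self.n_boot,
            "n_redraws": self.n_redraws,
            "seed_entropy": self.seed_entropy,
            "outcomes": {
                k: {
                    "c_apparent": v.c_apparent,
                    "c_corrected": v.c_corrected,
                    "c_ci": list(v.c_ci),
                    "ici_apparent": v.ici_apparent,
                    "ici_corrected": v.ici_corrected,
                    "ici_ci": list(v.ici_ci),
                    "calibration_curve": [list(pt) for pt in v.calibration_curve],
                }
                for k, v in self.per_outcome.items()
            },
        }


def internal_validate(
    model: FittedModel,
    table: pd.DataFrame,
    n_boot: int = 1000,
    seed=None,
    loess_frac: float = 0.75,
    max_curve_points: int = 200,
) -> ValidationReport:
    """Bootstrap optimism correction of the per-outcome one-vs-rest
    c-statistic and ICI.

    Each replicate resamples rows with replacement, refits the model
    coefficients (structure fixed), and measures performance on the
    replicate minus performance of the refit on the original table;
    corrected = apparent - mean optimism, with percentile confidence
    intervals from the per-replicate corrected values. Replicates
    missing either outcome class are redrawn (counted, capped)."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    codes = status_codes(table["true_status"])
    X = build_design(model.terms, table)
    n = len(table)

    p_app = _probabilities(model.intercepts, model.coef, X)
    apparent: dict[str, tuple[float, float]] = {}
    curves: dict[str, list[tuple[float, float]]] = {}
    for j, outcome in enumerate(OUTCOMES, start=1):
        y = codes == j
        c_app = c_statistic(p_app[:, j], y)
        ici_app = integrated_calibration_index(p_app[:, j], y, frac=loess_frac)
        apparent[outcome] = (c_app, ici_app)
        order = np.argsort(p_app[:, j], kind="stable")
        sm = _loess_observed(p_app[:, j], y.astype(float), loess_frac)
        idx = order[np.linspace(0, n - 1, min(max_curve_points, n)).astype(int)]
        curves[outcome] = [(float(p_app[i, j]), float(sm[i])) for i in idx]

    opt = {o: {"c": [], "ici": []} for o in OUTCOMES}
    redraws = 0
    max_attempts = 10 * n_boot
    attempts = 0
    done = 0
    while done < n_boot:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"exceeded bootstrap redraw cap ({max_attempts}); outcome too rare"
            )
        attempts += 1
        idx = rng.integers(0, n, n)
        cb = codes[idx]
        if any((cb == j).sum() == 0 for j in (0, 1, 2)):
            redraws += 1
            continue
        Xb = X[idx]
        fit_b = _fit_core(Xb, cb, ridge=model.ridge, warm=(model.intercepts, model.coef))
        p_boot = _probabilities(fit_b.intercepts, fit_b.coef, Xb)
        p_orig = _probabilities(fit_b.intercepts, fit_b.coef, X)
        for j, outcome in enumerate(OUTCOMES, start=1):
            yb = cb == j
            y = codes == j
            opt[outcome]["c"].append(
                c_statistic(p_boot[:, j], yb) - c_statistic(p_orig[:, j], y)
            )
            opt[outcome]["ici"].append(
                integrated_calibration_index(p_boot[:, j], yb, frac=loess_frac)
                - integrated_calibration_index(p_orig[:, j], y, frac=loess_frac)
            )
        done += 1

    per_outcome = {}
    for outcome in OUTCOMES:
        c_app, ici_app = apparent[outcome]
        c_opt = np.asarray(opt[outcome]["c"])
        ici_opt = np.asarray(opt[outcome]["ici"])
        c_dist = np.clip(c_app - c_opt, 0.0, 1.0)
        ici_dist = np.maximum(ici_app - ici_opt, 0.0)
        per_outcome[outcome] = OutcomeValidation(
            c_apparent=c_app,
            c_corrected=float(np.clip(c_app - c_opt.mean(), 0.0, 1.0)),
            c_ci=(float(np.percentile(c_dist, 2.5)), float(np.percentile(c_dist, 97.5))),
            ici_apparent=ici_app,
            ici_corrected=float(max(ici_app - ici_opt.mean(), 0.0)),
            ici_ci=(
                float(np.percentile(ici_dist, 2.5)),
                float(np.percentile(ici_dist, 97.5)),
            ),
            calibration_curve=curves[outcome],
        )
    return ValidationReport(
        per_outcome=per_outcome,
        n_boot=n_boot,
        n_redraws=redraws,
        seed_entropy=str(seed),
    )
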