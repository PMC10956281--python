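"""Operating characteristics of binary classifiers from 2x2 tables."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError


@dataclass(frozen=True)
class ContingencyTable:
    """Cross-tabulation of an assigned status against the true status."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.total == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def scaled(self, k: float) -> "ContingencyTable":
        return ContingencyTable(
            int(self.tp * k), int(self.fp * k), int(self.fn * k), int(self.tn * k)
        )


@dataclass(frozen=True)
class AccuracyStats:
    """Sensitivity / specificity / predictive values / likelihood ratios,
    held at full precision; rounding is applied only when formatting."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    plr: float
    nlr: float
    ppv_defined: bool = True
    npv_defined: bool = True


def contingency_from_vectors(assigned, truth) -> ContingencyTable:
    assigned = np.asarray(assigned, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if assigned.shape != truth.shape:
        raise ValueError("assigned and truth must have equal length")
    return ContingencyTable(
        tp=int((assigned & truth).sum()),
        fp=int((assigned & ~truth).sum()),
        fn=int((~assigned & truth).sum()),
        tn=int((~assigned & ~truth).sum()),
    )


def compute_accuracy(t: ContingencyTable) -> AccuracyStats:
    """Derive operating characteristics from a 2x2 table.

    Both true classes must be represented. The positive likelihood ratio
    is +inf when there are no false positives; an undefined predictive
    value (empty assigned margin) is flagged and reported as NaN.
    """
    if t.tp + t.fn == 0:
        raise DegenerateInputError("no truly positive records (tp + fn = 0)")
    if t.fp + t.tn == 0:
        raise DegenerateInputError("no truly negative records (fp + tn = 0)")
    sens = t.tp / (t.tp + t.fn)
    spec = t.tn / (t.fp + t.tn)
    ppv_defined = t.tp + t.fp > 0
    npv_defined = t.fn + t.tn > 0
    ppv = t.tp / (t.tp + t.fp) if ppv_defined else math.nan
    npv = t.tn / (t.fn + t.tn) if npv_defined else math.nan
    plr = sens / (1.0 - spec) if spec < 1.0 else math.inf
    nlr = (1.0 - sens) / spec if spec > 0 else math.inf
    return AccuracyStats(sens, spec, ppv, npv, plr, nlr, ppv_defined, npv_defined)


def _fmt_pct(x: float) -> str:
    return "undefined" if math.isnan(x) else f"{100.0 * x:.1f}%"


def _fmt_lr(x: float) -> str:
    return "inf" if math.isinf(x) else f"{x:.1f}"


def format_accuracy_block(label: str, t: ContingencyTable) -> str:
    """Render a text report block (counts plus 1-decimal statistics)."""
    s = compute_accuracy(t)
    lines = [
        label,
        f"            true +   true -",
        f"assigned +  {t.tp:>8d} {t.fp:>8d}    Sens {_fmt_pct(s.sensitivity)}  Spec {_fmt_pct(s.specificity)}",
        f"assigned -  {t.fn:>8d} {t.tn:>8d}    +PV {_fmt_pct(s.ppv)}  -PV {_fmt_pct(s.npv)}",
        f"                                +LR {_fmt_lr(s.plr)}  -LR {_fmt_lr(s.nlr)}",
    ]
    return "\n".join(lines)
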