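"""Synthetic hospitalization cohort generator.

Produces admission-level tables with a 3-level true procedure status
(``incontinent`` / ``continent`` / ``none``), two boolean procedure-code
flags with configurable error structure, and ~30 covariates whose
per-class marginals default to the published study-cohort values.

Class sizes are exact (fixed composition, not multinomial draws) so the
only Monte-Carlo noise in a generated table comes from the covariate and
code-flag draws.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SpecificationError

CLASSES = ("incontinent", "continent", "none")
N_COMORBIDITIES = 21

COMORBIDITY_COLUMNS = tuple(f"comorbidity_{j:02d}" for j in range(1, N_COMORBIDITIES + 1))

BINARY_COVARIATES = (
    "sex_male",
    "bladder_cancer_registry",
    "bladder_cancer_abstract",
    "elective",
    "urology_service",
    "transfusion",
    "general_anesthetic",
    "main_or_procedure",
    "unplanned_return_or_28d",
    "discharge_home_no_supports",
    "death_or_readmit_28d",
)

CONTINUOUS_COVARIATES = ("age", "operative_time", "acute_los")

COLUMN_ORDER = (
    ("true_status", "code_incontinent", "code_continent")
    + CONTINUOUS_COVARIATES
    + BINARY_COVARIATES
    + COMORBIDITY_COLUMNS
)

MIN_AGE = 18.0


@dataclass
class ClassParams:
    """Covariate distribution parameters for one true-status class.

    Continuous families: age is truncated normal (>= 18); operative time
    is two-part (point mass at zero + log-normal positive part); acute
    length of stay is log-normal. Binary covariates and comorbidity flags
    are independent Bernoulli given class.
    """

    age_mean: float
    age_sd: float
    operative_time_p_zero: float
    operative_time_median: float
    operative_time_sigma: float
    acute_los_median: float
    acute_los_sigma: float
    binary_probs: dict[str, float]
    comorbidity_probs: tuple[float, ...]

    def validate(self) -> None:
        probs = dict(self.binary_probs)
        probs["operative_time_p_zero"] = self.operative_time_p_zero
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise SpecificationError(f"probability out of [0,1] for {name!r}: {p}")
        for p in self.comorbidity_probs:
            if not 0.0 <= p <= 1.0:
                raise SpecificationError(f"comorbidity probability out of [0,1]: {p}")
        if len(self.comorbidity_probs) != N_COMORBIDITIES:
            raise SpecificationError(
                f"expected {N_COMORBIDITIES} comorbidity probabilities, "
                f"got {len(self.comorbidity_probs)}"
            )
        if set(self.binary_probs) != set(BINARY_COVARIATES):
            missing = set(BINARY_COVARIATES) - set(self.binary_probs)
            extra = set(self.binary_probs) - set(BINARY_COVARIATES)
            raise SpecificationError(f"binary_probs mismatch: missing={missing}, extra={extra}")
        if self.age_sd <= 0 or self.operative_time_sigma < 0 or self.acute_los_sigma < 0:
            raise SpecificationError("scale parameters must be positive")


@dataclass
class CodeParams:
    """Error structure of one procedure-code flag.

    sensitivity: P(flag | true status is this diversion type).
    cross_rate: P(flag | true status is the *other* diversion type).
    False positives among the no-procedure class are specified either as
    a per-admission rate (``fp_rate_none``) or as an expected *count*
    (``fp_expected_none``); a count target keeps the code's 2x2
    operating structure fixed when the no-procedure class is scaled
    down, mirroring how the case classes are preserved.
    differential: when True, those false positives are concentrated in
    admissions that resemble the procedure (urology service AND elective
    AND main-OR); the expected count is preserved. When False they are
    uniform over the class.
    """

    sensitivity: float
    cross_rate: float
    fp_rate_none: float | None = None
    fp_expected_none: float | None = None
    differential: bool = True

    def validate(self) -> None:
        for name in ("sensitivity", "cross_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecificationError(f"{name} out of [0,1]: {v}")
        if (self.fp_rate_none is None) == (self.fp_expected_none is None):
            raise SpecificationError(
                "exactly one of fp_rate_none / fp_expected_none must be set"
            )
        if self.fp_rate_none is not None and not 0.0 <= self.fp_rate_none <= 1.0:
            raise SpecificationError(f"fp_rate_none out of [0,1]: {self.fp_rate_none}")
        if self.fp_expected_none is not None and self.fp_expected_none < 0:
            raise SpecificationError("fp_expected_none must be >= 0")

    def expected_fp(self, n_none: int) -> float:
        if self.fp_expected_none is not None:
            return self.fp_expected_none
        return self.fp_rate_none * n_none


@dataclass
class CohortSpec:
    """Full generative specification for a synthetic cohort.

    ``similar_fraction`` carves out a subpopulation of the no-procedure
    class drawn from ``similar_params`` — admissions for comparable
    major surgery (urology service, elective, main OR, long operative
    times). This overlap is what makes code false positives and
    threshold-classifier false positives realistic; the remaining bulk
    parameters are chosen so the class marginals still match their
    targets.
    """

    n_incontinent: int
    n_continent: int
    n_none: int
    class_params: dict[str, ClassParams]
    code_params: dict[str, CodeParams]
    similar_fraction: float = 0.0
    similar_params: ClassParams | None = None
    scale_factor: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.scale_factor <= 0:
            raise SpecificationError(f"scale_factor must be > 0, got {self.scale_factor}")
        if not 0.0 <= self.similar_fraction < 1.0:
            raise SpecificationError("similar_fraction must be in [0, 1)")
        if self.similar_fraction > 0:
            if self.similar_params is None:
                raise SpecificationError("similar_fraction > 0 requires similar_params")
            self.similar_params.validate()
        for n in (self.n_incontinent, self.n_continent, self.n_none):
            if n < 0:
                raise SpecificationError(f"class counts must be >= 0, got {n}")
        counts = self.scaled_counts()
        if sum(counts.values()) <= 0:
            raise SpecificationError("total cohort size must be positive")
        if counts["incontinent"] < 1 or counts["continent"] < 1:
            raise SpecificationError(
                "scaled cystectomy class counts must be >= 1 "
                f"(got {counts['incontinent']}/{counts['continent']})"
            )
        if set(self.class_params) != set(CLASSES):
            raise SpecificationError(f"class_params must have keys {CLASSES}")
        if set(self.code_params) != {"incontinent", "continent"}:
            raise SpecificationError("code_params must have keys incontinent/continent")
        for cp in self.class_params.values():
            cp.validate()
        for cp in self.code_params.values():
            cp.validate()

    def scaled_counts(self) -> dict[str, int]:
        return {
            "incontinent": round(self.scale_factor * self.n_incontinent),
            "continent": round(self.scale_factor * self.n_continent),
            "none": round(self.scale_factor * self.n_none),
        }

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        d = dict(d)
        d["class_params"] = {
            k: ClassParams(**{**v, "comorbidity_probs": tuple(v["comorbidity_probs"])})
            if not isinstance(v, ClassParams)
            else v
            for k, v in d["class_params"].items()
        }
        d["code_params"] = {
            k: CodeParams(**v) if not isinstance(v, CodeParams) else v
            for k, v in d["code_params"].items()
        }
        sp = d.get("similar_params")
        if sp is not None and not isinstance(sp, ClassParams):
            d["similar_params"] = ClassParams(
                **{**sp, "comorbidity_probs": tuple(sp["comorbidity_probs"])}
            )
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _lognormal_sigma_from_iqr(q1: float, q3: float) -> float:
    """Sigma of a log-normal with the given quartiles (median-free)."""
    return float(np.log(q3 / q1) / (2.0 * stats.norm.ppf(0.75)))


# Comorbidity marginals: (probability in the no-procedure class,
# odds ratio for incontinent class, odds ratio for continent class).
# Invented (the study reports no comorbidity marginals); chosen to span
# prevalences 2-25%, keep every true association away from the null,
# and give the two diversion types distinct profiles — so that
# cross-coding one type as the other produces measurable bias, as the
# two types' published characteristics differ.
_COMORBIDITY_TABLE = (
    (0.25, 2.6, 1.4),
    (0.20, 1.4, 2.6),
    (0.18, 0.50, 0.70),
    (0.15, 2.8, 1.5),
    (0.12, 0.70, 0.45),
    (0.10, 3.0, 1.5),
    (0.10, 1.5, 3.0),
    (0.08, 2.4, 1.4),
    (0.08, 1.4, 2.4),
    (0.07, 2.8, 1.4),
    (0.06, 0.45, 0.70),
    (0.06, 2.6, 1.4),
    (0.05, 1.4, 2.6),
    (0.05, 2.4, 1.4),
    (0.05, 0.70, 0.45),
    (0.04, 2.6, 1.4),
    (0.04, 1.4, 2.6),
    (0.03, 2.8, 1.4),
    (0.03, 0.50, 0.70),
    (0.03, 3.0, 1.4),
    (0.02, 2.0, 1.8),
)


def _odds_shift(p0: float, odds_ratio: float) -> float:
    o = odds_ratio * p0 / (1.0 - p0)
    return o / (1.0 + o)


def default_spec(seed: int = 0) -> CohortSpec:
    """Generative spec whose marginals reproduce the published study
    cohort: 278 / 222 / 428,197 admissions, per-class covariate means
    and medians, and code flags with expected 2x2 tables
    (incontinent: TP 270 / FP 191; continent: TP 222 / FP 237).

    Partially suppressed cells in the source table (small-cell
    suppression) and the unreported zero-inflation of operative time in
    the no-procedure class are approximated; see parameter comments.
    """
    como_none = tuple(p for p, _, _ in _COMORBIDITY_TABLE)
    como_inc = tuple(_odds_shift(p, orr) for p, orr, _ in _COMORBIDITY_TABLE)
    como_cont = tuple(_odds_shift(p, orr) for p, _, orr in _COMORBIDITY_TABLE)

    class_params = {
        "incontinent": ClassParams(
            age_mean=71.2,
            age_sd=10.4,
            operative_time_p_zero=0.0,
            operative_time_median=526.0,
            operative_time_sigma=_lognormal_sigma_from_iqr(468.0, 590.0),
            acute_los_median=11.0,
            acute_los_sigma=_lognormal_sigma_from_iqr(8.0, 19.0),
            binary_probs={
                "sex_male": 0.723,
                "bladder_cancer_registry": 0.788,
                "bladder_cancer_abstract": 0.842,
                "elective": 0.953,
                "urology_service": 0.993,
                "transfusion": 0.594,
                "general_anesthetic": 0.953,
                "main_or_procedure": 0.989,
                "unplanned_return_or_28d": 0.076,
                "discharge_home_no_supports": 0.129,
                "death_or_readmit_28d": 0.090,
            },
            comorbidity_probs=como_inc,
        ),
        "continent": ClassParams(
            age_mean=63.6,
            age_sd=8.5,
            operative_time_p_zero=0.0,
            operative_time_median=641.0,
            operative_time_sigma=_lognormal_sigma_from_iqr(576.0, 695.0),
            acute_los_median=10.0,
            acute_los_sigma=_lognormal_sigma_from_iqr(8.0, 19.0),
            binary_probs={
                "sex_male": 0.797,
                "bladder_cancer_registry": 0.919,
                "bladder_cancer_abstract": 0.982,
                "elective": 0.982,
                "urology_service": 1.0,
                "transfusion": 0.550,
                "general_anesthetic": 0.968,
                "main_or_procedure": 1.0,
                "unplanned_return_or_28d": 0.086,
                "discharge_home_no_supports": 0.216,
                "death_or_readmit_28d": 0.086,
            },
            comorbidity_probs=como_cont,
        ),
    }

    # similar-surgery subpopulation of the no-procedure class (other
    # major elective urologic operations); the bulk probabilities below
    # are solved so the class marginal equals its target:
    #   bulk = (target - f * similar) / (1 - f)
    similar_fraction = 0.01
    similar_binary = {
        "sex_male": 0.60,
        "bladder_cancer_registry": 0.30,
        "bladder_cancer_abstract": 0.20,
        "elective": 0.95,
        "urology_service": 1.0,
        "transfusion": 0.35,
        "general_anesthetic": 0.90,
        "main_or_procedure": 1.0,
        "unplanned_return_or_28d": 12.0 / 428_197.0,
        "discharge_home_no_supports": 0.35,
        "death_or_readmit_28d": 0.088,
    }
    none_targets = {
        "sex_male": 0.405,
        "bladder_cancer_registry": 0.014,
        "bladder_cancer_abstract": 0.006,
        "elective": 0.334,
        "urology_service": 0.049,
        "transfusion": 0.125,
        "general_anesthetic": 0.268,
        "main_or_procedure": 0.340,
        "unplanned_return_or_28d": 12.0 / 428_197.0,
        "discharge_home_no_supports": 0.623,
        "death_or_readmit_28d": 0.088,
    }
    f = similar_fraction
    bulk_binary = {
        k: min(1.0, max(0.0, (none_targets[k] - f * similar_binary[k]) / (1.0 - f)))
        for k in none_targets
    }
    similar_params = ClassParams(
        age_mean=66.0,
        age_sd=12.0,
        operative_time_p_zero=0.0,
        operative_time_median=400.0,
        operative_time_sigma=0.35,
        acute_los_median=8.0,
        acute_los_sigma=0.6,
        binary_probs=similar_binary,
        comorbidity_probs=como_none,
    )
    class_params["none"] = ClassParams(
        # bulk of the no-procedure class; age mean solved as for binaries
        age_mean=(57.5 - f * 66.0) / (1.0 - f),
        age_sd=20.6,
        # zero-inflation chosen with the positive-part median so the
        # class quartiles of operative time are ~(0, 0, 113) minutes
        operative_time_p_zero=0.55 / (1.0 - f),
        operative_time_median=130.0,
        operative_time_sigma=1.0,
        acute_los_median=3.0,
        acute_los_sigma=_lognormal_sigma_from_iqr(2.0, 7.0),
        binary_probs=bulk_binary,
        comorbidity_probs=como_none,
    )
    code_params = {
        "incontinent": CodeParams(
            sensitivity=270.0 / 278.0,
            cross_rate=63.0 / 222.0,
            fp_expected_none=128.0,
        ),
        "continent": CodeParams(
            sensitivity=1.0,
            cross_rate=150.0 / 278.0,
            fp_expected_none=87.0,
        ),
    }
    return CohortSpec(
        n_incontinent=278,
        n_continent=222,
        n_none=428_197,
        class_params=class_params,
        code_params=code_params,
        similar_fraction=similar_fraction,
        similar_params=similar_params,
        seed=seed,
    )


def test_profile_spec(seed: int = 0, n_none: int = 50_000) -> CohortSpec:
    """Scaled-down spec for tests and the acceptance run: the
    no-procedure class is shrunk to ``n_none`` while both cystectomy
    class counts are kept at full size so the prediction model retains
    its events. Code error rates are unchanged (per-admission rates, so
    expected false-positive counts scale with the class)."""
    spec = default_spec(seed=seed)
    spec.n_none = n_none
    return spec


def _draw_class_block(
    params: ClassParams, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    a = (MIN_AGE - params.age_mean) / params.age_sd
    cols["age"] = stats.truncnorm.rvs(
        a, np.inf, loc=params.age_mean, scale=params.age_sd, size=n, random_state=rng
    )
    zero = rng.random(n) < params.operative_time_p_zero
    optime = np.exp(
        np.log(params.operative_time_median) + params.operative_time_sigma * rng.standard_normal(n)
    )
    optime[zero] = 0.0
    cols["operative_time"] = optime
    cols["acute_los"] = np.exp(
        np.log(params.acute_los_median) + params.acute_los_sigma * rng.standard_normal(n)
    )
    for name in BINARY_COVARIATES:
        cols[name] = rng.random(n) < params.binary_probs[name]
    for name, p in zip(COMORBIDITY_COLUMNS, params.comorbidity_probs):
        cols[name] = rng.random(n) < p
    return cols


def generate_cohort(spec: CohortSpec, log: list[str] | None = None) -> pd.DataFrame:
    """Generate a cohort table with exact per-class counts.

    Deterministic given ``spec.seed``. Rows are shuffled so class blocks
    are not contiguous. Code flags are assigned by :func:`assign_codes`
    from a child stream of the same seed.
    """
    spec.validate()
    counts = spec.scaled_counts()
    seq = np.random.SeedSequence(spec.seed)
    cov_seed, shuffle_seed, code_seed = seq.spawn(3)
    rng = np.random.default_rng(cov_seed)

    blocks = []
    for cls in CLASSES:
        n = counts[cls]
        if cls == "none" and spec.similar_fraction > 0:
            n_sim = round(spec.similar_fraction * n)
            for params, m in (
                (spec.class_params["none"], n - n_sim),
                (spec.similar_params, n_sim),
            ):
                block = pd.DataFrame(_draw_class_block(params, m, rng))
                block.insert(0, "true_status", cls)
                blocks.append(block)
            continue
        block = pd.DataFrame(_draw_class_block(spec.class_params[cls], n, rng))
        block.insert(0, "true_status", cls)
        blocks.append(block)
    table = pd.concat(blocks, ignore_index=True)

    order = np.random.default_rng(shuffle_seed).permutation(len(table))
    table = table.iloc[order].reset_index(drop=True)
    table["true_status"] = pd.Categorical(table["true_status"], categories=CLASSES)

    table = assign_codes(table, spec.code_params, seed=code_seed, log=log)
    if log is not None:
        log.append(f"generated cohort: {counts} (seed={spec.seed})")
    return table[list(COLUMN_ORDER)]


def assign_codes(
    table: pd.DataFrame,
    code_params: Mapping[str, CodeParams],
    seed,
    log: list[str] | None = None,
) -> pd.DataFrame:
    """Set the two procedure-code flags given true status.

    True positives arise at ``sensitivity`` within the matching class,
    cross-coded positives at ``cross_rate`` within the other cystectomy
    class, and false positives within the no-procedure class at
    ``fp_rate_none`` — either uniformly or (``differential=True``)
    concentrated in urology/elective/main-OR admissions.
    """
    rng = np.random.default_rng(seed)
    table = table.copy()
    status = np.asarray(table["true_status"].astype(str))
    none_mask = status == "none"
    similar = (
        np.asarray(table["urology_service"], dtype=bool)
        & np.asarray(table["elective"], dtype=bool)
        & np.asarray(table["main_or_procedure"], dtype=bool)
    )
    for diversion in ("incontinent", "continent"):
        cp = code_params[diversion]
        cp.validate()
        other = "continent" if diversion == "incontinent" else "incontinent"
        p = np.zeros(len(table))
        p[status == diversion] = cp.sensitivity
        p[status == other] = cp.cross_rate
        n_none = int(none_mask.sum())
        expected_fp = cp.expected_fp(n_none) if n_none else 0.0
        if cp.differential:
            eligible = none_mask & similar
            n_eligible = int(eligible.sum())
            if n_eligible > 0:
                p[eligible] = min(1.0, expected_fp / n_eligible)
            elif n_none:  # nothing resembles the procedure: fall back to uniform
                p[none_mask] = min(1.0, expected_fp / n_none)
        elif n_none:
            p[none_mask] = min(1.0, expected_fp / n_none)
        flag = rng.random(len(table)) < p
        table[f"code_{diversion}"] = flag
        if log is not None:
            tp = int(flag[status == diversion].sum())
            fp = int(flag[status != diversion].sum())
            log.append(f"code_{diversion}: realized TP={tp} FP={fp}")
    return table


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    table["true_status"] = pd.Categorical(table["true_status"], categories=CLASSES)
    for col in table.columns:
        if col.startswith("code_") or col in BINARY_COVARIATES or col in COMORBIDITY_COLUMNS:
            table[col] = table[col].astype(bool)
    return table
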