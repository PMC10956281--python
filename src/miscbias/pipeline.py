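"""End-to-end study orchestration: simulate -> fit -> validate ->
assign -> bias -> report, reproducible from one master seed."""

from __future__ import annotations

import dataclasses
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accuracy as acc
from . import assignment as asg
from . import bias as bias_mod
from . import cohort as coh
from . import model as mod
from .errors import DegenerateInputError, SpecificationError

DIVERSIONS = ("incontinent", "continent")


def default_candidates() -> list[mod.CandidateVariable]:
    """Candidate covariates in priority rank order (most procedure-
    predictive first, mirroring a clinician ranking)."""
    ranked = [
        ("code_incontinent", "binary"),
        ("code_continent", "binary"),
        ("urology_service", "binary"),
        ("elective", "binary"),
        ("bladder_cancer_abstract", "binary"),
        ("acute_los", "continuous"),
        ("unplanned_return_or_28d", "binary"),
        ("bladder_cancer_registry", "binary"),
        ("operative_time", "continuous"),
        ("main_or_procedure", "binary"),
        ("age", "continuous"),
        ("transfusion", "binary"),
        ("general_anesthetic", "binary"),
        ("sex_male", "binary"),
        ("discharge_home_no_supports", "binary"),
    ]
    return [
        mod.CandidateVariable(name=n, rank=i + 1, kind=k) for i, (n, k) in enumerate(ranked)
    ]


@dataclass
class RunConfig:
    spec: coh.CohortSpec
    candidates: list[mod.CandidateVariable] = field(default_factory=default_candidates)
    battery: list[bias_mod.StatisticDefinition] = field(
        default_factory=bias_mod.default_battery
    )
    alpha: float = 0.05
    ridge: float = 0.0
    n_boot_validation: int = 1000
    n_boot_imputation: int = 1000
    threshold_criterion: str = "youden_j"
    smse_mode: str = "analysis"
    exclusive_imputation: bool = True
    loess_frac: float = 0.75
    seed: int = 0
    # df-budget planning assumptions: anticipated admissions and events
    # per diversion type (a protocol constant, independent of the
    # realized cohort scale)
    planning_n: int = 429_000
    planning_events: int = 250

    def validate(self) -> None:
        self.spec.validate()
        if not self.candidates:
            raise SpecificationError("candidate list must be non-empty")
        if self.n_boot_validation < 2 or self.n_boot_imputation < 2:
            raise SpecificationError("bootstrap counts must be >= 2")


def default_config(seed: int = 0) -> RunConfig:
    """Full-scale protocol (428,697 admissions, 1000 bootstraps)."""
    return RunConfig(spec=coh.default_spec(seed=seed), seed=seed)


def test_config(seed: int = 0, n_none: int = 50_000, n_boot: int = 200) -> RunConfig:
    """Scaled-down profile: the no-procedure class shrunk to ``n_none``
    (case counts preserved) and both bootstrap loops at ``n_boot``."""
    return RunConfig(
        spec=coh.test_profile_spec(seed=seed, n_none=n_none),
        n_boot_validation=n_boot,
        n_boot_imputation=n_boot,
        seed=seed,
    )


def config_from_yaml(path) -> RunConfig:
    """Build a run configuration from a YAML file.

    Keys: ``profile`` ("paper" | "test"), ``seed``, and optional
    overrides (``n_none``, ``n_boot_validation``, ``n_boot_imputation``,
    ``alpha``, ``ridge``, ``threshold_criterion``, ``smse_mode``,
    ``exclusive_imputation``, ``loess_frac``).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    profile = raw.pop("profile", "test")
    seed = int(raw.pop("seed", 0))
    if profile == "paper":
        cfg = default_config(seed=seed)
    elif profile == "test":
        cfg = test_config(seed=seed, n_none=int(raw.pop("n_none", 50_000)))
    else:
        raise SpecificationError(f"unknown profile {profile!r}")
    for key in (
        "alpha",
        "ridge",
        "n_boot_validation",
        "n_boot_imputation",
        "threshold_criterion",
        "smse_mode",
        "exclusive_imputation",
        "loess_frac",
    ):
        if key in raw:
            setattr(cfg, key, raw.pop(key))
    if raw:
        raise SpecificationError(f"unknown config keys: {sorted(raw)}")
    cfg.validate()
    return cfg


@dataclass
class StudyResult:
    config: RunConfig
    table: pd.DataFrame
    budget: mod.DfBudget
    model: mod.FittedModel
    validation: mod.ValidationReport
    p_hat: pd.DataFrame
    code_tables: dict[str, acc.ContingencyTable]
    thresholds: dict[str, asg.ThresholdRule]
    categorical_tables: dict[str, acc.ContingencyTable]
    truth_stats: dict[str, list[bias_mod.StatisticEstimate]]
    method_stats: dict[str, dict[str, list[bias_mod.StatisticEstimate]]]
    bi_results: dict[str, list[asg.BIResult]]
    smse: dict[str, list[bias_mod.SMSERecord]]
    comparison: dict[str, bias_mod.MethodComparison | None]  # None when degenerate
    log: list[str]

    # -- export ----------------------------------------------------------
    def statistics_frame(self) -> pd.DataFrame:
        rows = []
        for div in DIVERSIONS:
            for est in self.truth_stats[div]:
                rows.append(self._stat_row(div, "truth", est))
            for method, ests in self.method_stats[div].items():
                if method == "bi":
                    continue
                for est in ests:
                    rows.append(self._stat_row(div, method, est))
            for r in self.bi_results[div]:
                rows.append(
                    dict(
                        diversion=div,
                        method="bi",
                        statistic=r.statistic,
                        beta=r.point,
                        se=math.nan,
                        ci_low=r.ci_low,
                        ci_high=r.ci_high,
                    )
                )
        return pd.DataFrame(rows)

    @staticmethod
    def _stat_row(div, method, est):
        half = 1.959963984540054 * est.se
        return dict(
            diversion=div,
            method=method,
            statistic=est.statistic,
            beta=est.beta,
            se=est.se,
            ci_low=est.beta - half,
            ci_high=est.beta + half,
        )

    def smse_frame(self) -> pd.DataFrame:
        rows = [
            dict(diversion=div, **dataclasses.asdict(r))
            for div in DIVERSIONS
            for r in self.smse[div]
        ]
        return pd.DataFrame(rows)

    def write(self, outdir, write_cohort: bool = True) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        if write_cohort:
            coh.write_cohort(self.table, out / "cohort.csv")
        self.model.save(out / "model.json")
        with open(out / "validation.json", "w") as fh:
            json.dump(self.validation.to_dict(), fh, indent=2)
        blocks = []
        counts = {}
        for div in DIVERSIONS:
            blocks.append(
                acc.format_accuracy_block(f"code classifier — {div}", self.code_tables[div])
            )
            blocks.append(
                acc.format_accuracy_block(
                    f"categorical (threshold) classifier — {div}",
                    self.categorical_tables[div],
                )
            )
            counts[f"code_{div}"] = dataclasses.asdict(self.code_tables[div])
            counts[f"categorical_{div}"] = dataclasses.asdict(self.categorical_tables[div])
        (out / "accuracy.txt").write_text("\n\n".join(blocks) + "\n")
        with open(out / "accuracy.json", "w") as fh:
            json.dump(counts, fh, indent=2)
        with open(out / "thresholds.json", "w") as fh:
            json.dump(
                {d: dataclasses.asdict(r) for d, r in self.thresholds.items()}, fh, indent=2
            )
        self.statistics_frame().to_csv(out / "statistics.csv", index=False)
        self.smse_frame().to_csv(out / "smse.csv", index=False)
        with open(out / "comparison.json", "w") as fh:
            json.dump(
                {d: (c.to_dict() if c is not None else None) for d, c in self.comparison.items()},
                fh,
                indent=2,
            )
        with open(out / "budget.json", "w") as fh:
            json.dump(
                {
                    "epv_df": self.budget.epv_df,
                    "precision_df": self.budget.precision_df,
                    "shrinkage_df": self.budget.shrinkage_df,
                    "optimism_df": self.budget.optimism_df,
                    "allowed_df": self.budget.allowed_df,
                    "assumptions": self.budget.assumptions,
                },
                fh,
                indent=2,
            )
        (out / "run_log.txt").write_text("\n".join(self.log) + "\n")


def run_study(config: RunConfig) -> StudyResult:
    """Execute the full protocol and return the in-memory bundle.

    Deterministic for a given config and master seed: every stochastic
    stage draws from a stream spawned from ``config.seed``.
    """
    config.validate()
    log: list[str] = [f"master seed: {config.seed}"]
    seq = np.random.SeedSequence(config.seed)
    seed_val, seed_bi_inc, seed_bi_cont = seq.spawn(3)
    t0 = time.perf_counter()

    def mark(stage):
        log.append(f"[{time.perf_counter() - t0:8.1f}s] {stage}")

    config.spec.seed = config.seed
    table = coh.generate_cohort(config.spec, log=log)
    mark(f"simulate: {len(table)} rows")

    status = table["true_status"].astype(str).to_numpy()
    truth = {d: status == d for d in DIVERSIONS}
    code_tables = {
        d: acc.contingency_from_vectors(asg.assign_by_code(table, d), truth[d])
        for d in DIVERSIONS
    }
    mark("code accuracy")

    budget = mod.compute_df_budget(n=config.planning_n, events=config.planning_events)
    log.append(
        f"df budget: epv={budget.epv_df:.1f} precision={budget.precision_df:.1f} "
        f"shrinkage={budget.shrinkage_df:.1f} optimism={budget.optimism_df:.1f} "
        f"allowed={budget.allowed_df:.1f}"
    )
    model = mod.forward_select(
        config.candidates, table, alpha=config.alpha, budget=budget, ridge=config.ridge
    )
    log.append(f"model terms: {[t.name for t in model.terms]}")
    mark("fit")

    validation = mod.internal_validate(
        model,
        table,
        n_boot=config.n_boot_validation,
        seed=seed_val,
        loess_frac=config.loess_frac,
    )
    for o, v in validation.per_outcome.items():
        log.append(
            f"validation {o}: c_app={v.c_apparent:.4f} c_corr={v.c_corrected:.4f} "
            f"ici_app={v.ici_apparent:.5f} ici_corr={v.ici_corrected:.5f}"
        )
    mark("validate")

    p_hat = mod.predict_probabilities(model, table)
    thresholds = {}
    categorical_tables = {}
    cat_status = {}
    for d in DIVERSIONS:
        p = p_hat[f"p_{d}"].to_numpy()
        rule = asg.find_threshold(p, truth[d], criterion=config.threshold_criterion, diversion=d)
        thresholds[d] = rule
        cat_status[d] = asg.assign_by_threshold(p, rule)
        categorical_tables[d] = acc.contingency_from_vectors(cat_status[d], truth[d])
        log.append(f"threshold {d}: tau={rule.tau:.6g} J={rule.youden_j:.4f}")
    mark("assign")

    truth_stats = {}
    method_stats = {}
    bi_results = {}
    smse_tables = {}
    comparisons = {}
    bi_seeds = {"incontinent": seed_bi_inc, "continent": seed_bi_cont}
    for d in DIVERSIONS:
        truth_stats[d] = bias_mod.compute_statistics(table, truth[d], config.battery, "truth")
        code_est = bias_mod.compute_statistics(
            table, asg.assign_by_code(table, d), config.battery, "code"
        )
        cat_est = bias_mod.compute_statistics(table, cat_status[d], config.battery, "categorical")
        bi = asg.bootstrap_impute(
            table,
            p_hat,
            config.battery,
            diversion=d,
            n_boot=config.n_boot_imputation,
            seed=bi_seeds[d],
            exclusive=config.exclusive_imputation,
            log=log,
        )
        bi_results[d] = bi
        kinds = {s.name: s.kind for s in config.battery}
        bi_est = [
            bias_mod.StatisticEstimate(r.statistic, kinds[r.statistic], r.point, math.nan, "bi")
            for r in bi
        ]
        method_stats[d] = {"code": code_est, "categorical": cat_est, "bi": bi_est}
        smse_tables[d] = bias_mod.smse_records(
            truth_stats[d], method_stats[d], mode=config.smse_mode, log=log
        )
        try:
            c = bias_mod.compare_methods(smse_tables[d], alpha=0.05, log=log)
        except DegenerateInputError as exc:
            # e.g. a method with (near-)zero SMSE throughout: nothing to
            # compare on the log scale
            c = None
            log.append(f"bias {d}: comparison degenerate ({exc})")
        comparisons[d] = c
        if c is not None:
            log.append(
                f"bias {d}: medians={ {m: round(v, 4) for m, v in c.median.items()} } "
                f"F={c.f_stat:.2f} p={c.p_value:.2e}"
            )
        mark(f"bias {d}")

    return StudyResult(
        config=config,
        table=table,
        budget=budget,
        model=model,
        validation=validation,
        p_hat=p_hat,
        code_tables=code_tables,
        thresholds=thresholds,
        categorical_tables=categorical_tables,
        truth_stats=truth_stats,
        method_stats=method_stats,
        bi_results=bi_results,
        smse=smse_tables,
        comparison=comparisons,
        log=log,
    )
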