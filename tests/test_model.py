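import json
import math

import numpy as np
import pandas as pd
import pytest

from miscbias import model as mod
from miscbias.errors import DegenerateInputError, SchemaError


# ---------------------------------------------------------------------------
# degrees-of-freedom budget
# ---------------------------------------------------------------------------


class TestDfBudget:
    def test_epv_criterion_is_events_over_epv(self):
        assert mod.compute_df_budget(429_000, 250).epv_df == 25.0
        assert mod.compute_df_budget(429_000, 100).epv_df == 10.0

    def test_epv_is_the_binding_criterion_at_protocol_scale(self):
        b = mod.compute_df_budget(429_000, 250)
        assert b.allowed_df == b.epv_df == 25.0
        assert b.precision_df > 25.0
        assert b.shrinkage_df > 25.0
        assert b.optimism_df > 25.0

    def test_reported_companion_criteria(self):
        # MAPE-inversion and shrinkage closed forms under the documented
        # default assumptions
        b = mod.compute_df_budget(429_000, 250)
        assert round(b.precision_df, 1) == 42.6
        assert round(b.shrinkage_df, 1) == 32.1

    def test_zero_events_rejected(self):
        with pytest.raises(DegenerateInputError):
            mod.compute_df_budget(1000, 0)

    def test_assumptions_logged(self):
        b = mod.compute_df_budget(10_000, 100)
        assert b.assumptions["epv"] == 10.0
        assert b.assumptions["prevalence"] == pytest.approx(0.01)


# ---------------------------------------------------------------------------
# fractional polynomials
# ---------------------------------------------------------------------------


def _simulate_fp_outcome(rng, transform, n=5000):
    """3-class outcome whose first logit is linear in transform(x)."""
    x = rng.lognormal(mean=1.0, sigma=0.7, size=n)
    t = transform(x)
    t = (t - t.mean()) / t.std()
    eta1 = -1.5 + 2.5 * t
    eta2 = -2.0 + 1.0 * t
    den = 1.0 + np.exp(eta1) + np.exp(eta2)
    u = rng.random(n)
    p1 = np.exp(eta1) / den
    p2 = np.exp(eta2) / den
    codes = np.where(u < p1, 1, np.where(u < p1 + p2, 2, 0))
    return x, codes


def _brute_force_fp_power(x, codes, powers=mod.FP_POWERS):
    """Independent oracle: statsmodels multinomial deviance per power."""
    import statsmodels.api as sm

    shift = mod.fp_shift(x)
    devs = {}
    for p in powers:
        X = sm.add_constant(mod.fp_transform(x, p, shift))
        fit = sm.MNLogit(codes, X).fit(disp=False, maxiter=200)
        devs[p] = -2.0 * fit.llf
    return min(devs, key=devs.get)


class TestSelectFP1:
    def test_log_generated_outcome_selects_log(self, rng):
        x, codes = _simulate_fp_outcome(rng, np.log)
        power, shift, flagged = mod.select_fp1(x, codes)
        assert power == 0.0
        assert not flagged
        assert _brute_force_fp_power(x, codes) == 0.0

    def test_linear_outcome_selects_identity(self, rng):
        x, codes = _simulate_fp_outcome(rng, lambda v: v)
        power, _, flagged = mod.select_fp1(x, codes)
        assert power == 1.0
        assert not flagged
        assert _brute_force_fp_power(x, codes) == 1.0

    def test_reciprocal_outcome_matches_oracle(self, rng):
        x, codes = _simulate_fp_outcome(rng, lambda v: 1.0 / v)
        power, _, _ = mod.select_fp1(x, codes)
        assert power == _brute_force_fp_power(x, codes)

    def test_constant_covariate_flagged(self):
        codes = np.array([0, 1, 2, 0, 1, 2])
        power, shift, flagged = mod.select_fp1(np.ones(6), codes)
        assert power == 1.0
        assert flagged

    def test_shift_makes_values_positive(self):
        x = np.array([0.0, 2.0, 4.0, 6.0])
        s = mod.fp_shift(x)
        assert (x + s > 0).all()
        assert s == 2.0  # smallest positive spacing
        assert mod.fp_shift(np.array([1.0, 2.0])) == 0.0


# ---------------------------------------------------------------------------
# forward selection
# ---------------------------------------------------------------------------


def _three_class_table(rng, n, informative_effect=2.0, n_noise=5):
    """One informative binary covariate + pure-noise binaries."""
    z = rng.random(n) < 0.3
    eta1 = -4.0 + informative_effect * z
    eta2 = -4.5 + informative_effect * z
    den = 1.0 + np.exp(eta1) + np.exp(eta2)
    u = rng.random(n)
    p1, p2 = np.exp(eta1) / den, np.exp(eta2) / den
    codes = np.where(u < p1, 1, np.where(u < p1 + p2, 2, 0))
    cols = {"informative": z}
    for j in range(n_noise):
        cols[f"noise_{j}"] = rng.random(n) < 0.5
    t = pd.DataFrame(cols)
    t["true_status"] = pd.Categorical.from_codes(
        codes, categories=["none", "incontinent", "continent"]
    )
    return t


def test_empty_candidates_gives_intercept_only(tiny_table):
    m = mod.forward_select([], tiny_table)
    assert m.terms == []
    p = mod.predict_probabilities(m, tiny_table)
    status = tiny_table["true_status"].astype(str)
    fracs = status.value_counts(normalize=True)
    assert p["p_incontinent"].iloc[0] == pytest.approx(fracs["incontinent"], rel=1e-3)
    assert p["p_none"].iloc[0] == pytest.approx(fracs["none"], rel=1e-3)


def test_informative_kept_noise_at_alpha_rate(rng):
    """Type-I inclusion simulation: each noise covariate should enter
    with probability ~ alpha. Pooled over replicates and noise columns;
    4-sigma binomial band around 0.05."""
    n_rep, n_noise = 60, 5
    kept_noise = 0
    kept_informative = 0
    for _ in range(n_rep):
        t = _three_class_table(rng, n=2500, n_noise=n_noise)
        cands = [mod.CandidateVariable("informative", 1, "binary")] + [
            mod.CandidateVariable(f"noise_{j}", j + 2, "binary") for j in range(n_noise)
        ]
        m = mod.forward_select(cands, t, alpha=0.05)
        names = {term.name for term in m.terms}
        kept_informative += "informative" in names
        kept_noise += sum(f"noise_{j}" in names for j in range(n_noise))
    assert kept_informative == n_rep
    rate = kept_noise / (n_rep * n_noise)
    se = math.sqrt(0.05 * 0.95 / (n_rep * n_noise))
    assert abs(rate - 0.05) < 4 * se


def test_candidates_offered_in_rank_order_and_traced(tiny_table):
    cands = [
        mod.CandidateVariable("elective", 2, "binary"),
        mod.CandidateVariable("code_incontinent", 1, "binary"),
    ]
    m = mod.forward_select(cands, tiny_table)
    assert [r["variable"] for r in m.trace] == ["code_incontinent", "elective"]


def test_duplicate_ranks_rejected(tiny_table):
    cands = [
        mod.CandidateVariable("elective", 1, "binary"),
        mod.CandidateVariable("sex_male", 1, "binary"),
    ]
    with pytest.raises(ValueError, match="rank"):
        mod.forward_select(cands, tiny_table)


def test_missing_column_names_it(tiny_table):
    with pytest.raises(SchemaError, match="no_such"):
        mod.forward_select([mod.CandidateVariable("no_such", 1, "binary")], tiny_table)


def test_df_budget_respected(tiny_table):
    budget = mod.DfBudget(epv_df=2.0, precision_df=9.0, shrinkage_df=9.0, optimism_df=9.0)
    cands = [
        mod.CandidateVariable(n, i + 1, "binary")
        for i, n in enumerate(
            ["code_incontinent", "code_continent", "urology_service", "elective"]
        )
    ]
    m = mod.forward_select(cands, tiny_table, budget=budget)
    assert len(m.terms) <= 2
    reasons = {r["variable"]: r["reason"] for r in m.trace}
    assert any(v == "df_budget" for v in reasons.values())


def test_loglik_nondecreasing_and_lrt_nonnegative(tiny_table):
    cands = [
        mod.CandidateVariable("code_incontinent", 1, "binary"),
        mod.CandidateVariable("code_continent", 2, "binary"),
        mod.CandidateVariable("acute_los", 3, "continuous"),
    ]
    m = mod.forward_select(cands, tiny_table)
    intercept_only = mod.forward_select([], tiny_table)
    assert m.loglik >= intercept_only.loglik
    for row in m.trace:
        assert row["lrt"] >= 0.0


def test_model_json_round_trip(tmp_path, tiny_table):
    cands = [
        mod.CandidateVariable("code_incontinent", 1, "binary"),
        mod.CandidateVariable("acute_los", 2, "continuous"),
    ]
    m = mod.forward_select(cands, tiny_table)
    path = tmp_path / "model.json"
    m.save(path)
    back = mod.FittedModel.load(path)
    assert [t.name for t in back.terms] == [t.name for t in m.terms]
    p1 = mod.predict_probabilities(m, tiny_table)
    p2 = mod.predict_probabilities(back, tiny_table)
    np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-12)
    json.loads(path.read_text())  # valid JSON on disk


def test_probability_triplets_sum_to_one(tiny_table):
    cands = [mod.CandidateVariable("code_incontinent", 1, "binary")]
    m = mod.forward_select(cands, tiny_table)
    p = mod.predict_probabilities(m, tiny_table)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
    assert (p.to_numpy() >= 0).all()


def test_predict_missing_column_raises_schema_error(tiny_table):
    m = mod.forward_select([mod.CandidateVariable("elective", 1, "binary")], tiny_table)
    with pytest.raises(SchemaError, match="elective"):
        mod.predict_probabilities(m, tiny_table.drop(columns=["elective"]))


# ---------------------------------------------------------------------------
# discrimination / calibration
# ---------------------------------------------------------------------------


def brute_force_concordance(p, y):
    """All-pairs concordance count with half credit for ties."""
    p, y = np.asarray(p, float), np.asarray(y, bool)
    pos, neg = p[y], p[~y]
    wins = ties = 0
    for a in pos:
        wins += (a > neg).sum()
        ties += (a == neg).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def test_c_statistic_equals_brute_force(rng):
    for _ in range(5):
        n = 300
        y = rng.random(n) < 0.3
        p = np.round(rng.random(n), 2)  # ties on purpose
        assert mod.c_statistic(p, y) == pytest.approx(brute_force_concordance(p, y), abs=1e-12)


def test_c_statistic_needs_both_classes():
    with pytest.raises(DegenerateInputError):
        mod.c_statistic(np.array([0.1, 0.2]), np.array([True, True]))


def test_constant_probability_gives_half():
    y = np.array([True, False, True, False])
    assert mod.c_statistic(np.full(4, 0.3), y) == 0.5


def test_ici_zero_for_perfectly_calibrated_step(rng):
    n = 4000
    p = np.where(rng.random(n) < 0.5, 0.05, 0.95)
    y = rng.random(n) < p
    ici = mod.integrated_calibration_index(p, y)
    assert ici < 0.03


def test_internal_validate_separable_data(rng):
    n = 3000
    x = rng.standard_normal(n)
    codes = np.where(x > 2.2, 1, np.where(x < -2.2, 2, 0))
    if (codes == 1).sum() < 5 or (codes == 2).sum() < 5:  # pragma: no cover
        pytest.skip("degenerate draw")
    t = pd.DataFrame({"x": x})
    t["true_status"] = pd.Categorical.from_codes(
        codes, categories=["none", "incontinent", "continent"]
    )
    m = mod.forward_select([mod.CandidateVariable("x", 1, "continuous")], t)
    rep = mod.internal_validate(m, t, n_boot=20, seed=5)
    for v in rep.per_outcome.values():
        assert v.c_corrected > 0.99
        assert v.ici_corrected < 0.02
        assert 0.0 <= v.c_ci[0] <= v.c_ci[1] <= 1.0


def test_internal_validate_intercept_only_c_is_half(tiny_table):
    m = mod.forward_select([], tiny_table)
    rep = mod.internal_validate(m, tiny_table, n_boot=5, seed=2)
    for v in rep.per_outcome.values():
        assert v.c_apparent == pytest.approx(0.5)


def test_internal_validate_rejects_tiny_n_boot(tiny_table):
    m = mod.forward_select([], tiny_table)
    with pytest.raises(ValueError):
        mod.internal_validate(m, tiny_table, n_boot=1)
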