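import numpy as np
import pandas as pd
import pytest

from partworth import (
    AttributeSpec,
    FitError,
    SeparationError,
    enumerate_full_factorial,
    fit_aggregate_logit,
    recode_monitoring,
    utility_table,
)
from partworth.estimate import ResponseParseError, utilities_by_attribute


def _two_by_two_responses():
    """One binary attribute; level A: 30 yes / 10 no, level B: 15 yes / 25 no."""
    attrs = [AttributeSpec("exposure", ("A", "B"))]
    profiles = enumerate_full_factorial(attrs)  # id 0 = A, id 1 = B
    rows = (
        [(0, "yes")] * 30 + [(0, "no")] * 10 + [(1, "yes")] * 15 + [(1, "no")] * 25
    )
    df = pd.DataFrame(
        {
            "respondent_id": range(len(rows)),
            "profile_id": [pid for pid, _ in rows],
            "sglt2": [y for _, y in rows],
        }
    )
    return attrs, profiles, df


@pytest.mark.parametrize(
    "value,expected", [("increase", 1), ("maintain", 0), ("decrease", 0)]
)
def test_recode_monitoring(value, expected):
    assert recode_monitoring(value) == expected


def test_recode_unknown_label_raises():
    with pytest.raises(ResponseParseError):
        recode_monitoring("sometimes")


def test_unknown_label_in_table_names_row():
    attrs, profiles, df = _two_by_two_responses()
    df.loc[17, "sglt2"] = "maybe"
    with pytest.raises(ResponseParseError, match="row 17"):
        fit_aggregate_logit(df, profiles, attrs, "sglt2")


class TestTwoByTwoOracle:
    """Saturated 2x2 logit equals the contingency-table closed form."""

    def test_or_equals_cross_product_ratio(self):
        attrs, profiles, df = _two_by_two_responses()
        fit = fit_aggregate_logit(df, profiles, attrs, "sglt2")
        ut = utility_table(fit)
        u = ut.set_index("level")["utility"]
        log_or = u["A"] - u["B"]
        assert np.exp(log_or) == pytest.approx((30 * 25) / (10 * 15), abs=1e-6)

    def test_wald_se_equals_cell_formula(self):
        attrs, profiles, df = _two_by_two_responses()
        fit = fit_aggregate_logit(df, profiles, attrs, "sglt2")
        # var(logOR) with effects coding: logOR = 2*beta1
        se_logor = 2 * np.sqrt(fit.cov[1, 1])
        expected = np.sqrt(1 / 30 + 1 / 10 + 1 / 15 + 1 / 25)
        assert se_logor == pytest.approx(expected, abs=1e-6)


def test_all_identical_outcomes_raise_separation():
    attrs, profiles, df = _two_by_two_responses()
    df["sglt2"] = "yes"
    with pytest.raises((SeparationError, FitError)):
        fit_aggregate_logit(df, profiles, attrs, "sglt2")


def test_perfect_predictor_raises_separation_naming_column():
    attrs, profiles, _ = _two_by_two_responses()
    rows = [(0, "yes")] * 40 + [(1, "no")] * 40
    df = pd.DataFrame(
        {
            "respondent_id": range(80),
            "profile_id": [p for p, _ in rows],
            "sglt2": [y for _, y in rows],
        }
    )
    with pytest.raises(SeparationError, match="exposure"):
        fit_aggregate_logit(df, profiles, attrs, "sglt2")


def test_row_order_invariance(study, study_design, study_responses):
    attrs, _ = study
    shuffled = study_responses.sample(frac=1.0, random_state=0).reset_index(drop=True)
    a = fit_aggregate_logit(study_responses, study_design.profiles, attrs, "monitoring")
    b = fit_aggregate_logit(shuffled, study_design.profiles, attrs, "monitoring")
    np.testing.assert_allclose(a.params, b.params, atol=1e-8)
    np.testing.assert_allclose(a.cov, b.cov, atol=1e-10)


def test_matches_statsmodels_reference(study, study_design, study_responses):
    """Independent cross-check: same MLE and covariance as statsmodels Logit."""
    import statsmodels.api as sm

    from partworth.design import encode_effects

    attrs, _ = study
    fit = fit_aggregate_logit(study_responses, study_design.profiles, attrs, "sglt2")
    design = encode_effects(study_design.profiles, attrs)
    row_of = {pid: i for i, pid in enumerate(design.profile_ids)}
    X = design.X[[row_of[p] for p in study_responses["profile_id"]]]
    y = (study_responses["sglt2"] == "yes").astype(float).to_numpy()
    ref = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-10)
    np.testing.assert_allclose(fit.params, ref.params, atol=1e-6)
    np.testing.assert_allclose(fit.cov, ref.cov_params(), atol=1e-6)
    assert fit.llf == pytest.approx(ref.llf, abs=1e-6)


def test_decoded_utilities_zero_sum(study, study_design, study_responses):
    attrs, _ = study
    fit = fit_aggregate_logit(study_responses, study_design.profiles, attrs, "monitoring")
    for u in utilities_by_attribute(fit).values():
        assert abs(u.sum()) < 1e-8


def test_missing_outcome_rows_dropped(study, study_design, study_responses):
    attrs, _ = study
    broken = study_responses.copy()
    broken.loc[broken.index[:50], "sglt2"] = np.nan
    fit = fit_aggregate_logit(broken, study_design.profiles, attrs, "sglt2")
    assert fit.n_obs == len(broken) - 50


def test_decoded_last_level_se_matches_bootstrap():
    """Delta-method SE of the reconstructed level vs a resampling oracle."""
    attrs = [AttributeSpec("drug", ("A", "B", "C"))]
    profiles = enumerate_full_factorial(attrs)
    rng = np.random.default_rng(7)
    pid = rng.integers(0, 3, size=600)
    true_u = np.array([0.4, -0.1, -0.3])
    y = rng.random(600) < 1 / (1 + np.exp(-true_u[pid]))
    df = pd.DataFrame(
        {
            "respondent_id": range(600),
            "profile_id": pid,
            "sglt2": np.where(y, "yes", "no"),
        }
    )
    fit = fit_aggregate_logit(df, profiles, attrs, "sglt2")
    se_c = utility_table(fit).set_index("level").loc["C", "se"]
    boot = []
    for _ in range(2000):
        idx = rng.integers(0, 600, size=600)
        bdf = df.iloc[idx].reset_index(drop=True)
        bdf["respondent_id"] = range(600)
        bfit = fit_aggregate_logit(bdf, profiles, attrs, "sglt2")
        boot.append(utility_table(bfit).set_index("level").loc["C", "utility"])
    assert se_c == pytest.approx(np.std(boot, ddof=1), rel=0.12)


def test_cluster_robust_covariance_stays_psd(study, study_design, study_responses):
    attrs, _ = study
    fit = fit_aggregate_logit(
        study_responses, study_design.profiles, attrs, "monitoring",
        cluster_robust=True,
    )
    eigvals = np.linalg.eigvalsh(fit.cov)
    assert eigvals.min() > -1e-12


def test_nonconverged_fit_refuses_decode(study, study_design, study_responses):
    attrs, _ = study
    fit = fit_aggregate_logit(
        study_responses, study_design.profiles, attrs, "monitoring", max_iter=1
    )
    assert not fit.converged
    with pytest.raises(FitError):
        utility_table(fit)
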