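"""Mixed models, logistic regression, t-tests, results table rendering."""

import warnings

import numpy as np
import pandas as pd
import pytest

from myotrace.assoc import (
    ModelSpec,
    fit_ap_mixed_model,
    fit_fibrosis_model,
    fit_logistic,
    format_text_table,
    render_results_table,
    ttest_drug_vs_spontaneous,
)
from myotrace.synth import COVARIATES, DEPENDENTS, CohortGeneratingModel, generate_cohort


@pytest.fixture(scope="module")
def cohort_table():
    table, _ = generate_cohort(seed=17)
    return table


def test_mixed_model_fit_basics(cohort_table):
    res = fit_ap_mixed_model(cohort_table, ModelSpec("APD90"))
    assert res.n_groups == 25 and res.n_obs == 375
    assert res.converged
    assert np.isfinite(res.estimate("stim_frequency"))
    assert 0.0 <= res.p_value("stim_frequency") <= 1.0
    assert np.isfinite(res.adjusted_r2)


def test_zero_patient_variance_matches_ols(cohort_table):
    """With no between-patient variance the mixed fit degenerates to OLS."""
    import statsmodels.formula.api as smf

    m = CohortGeneratingModel()
    m.patient_sd = {d: 0.0 for d in m.patient_sd}
    table, _ = generate_cohort(m, 25, 3, seed=21)
    spec = ModelSpec("APD90")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = fit_ap_mixed_model(table, spec)
        formula = "APD90 ~ " + " + ".join(c for c in COVARIATES
                                          if table[c].nunique() > 1)
        ols = smf.ols(formula, table).fit()
    for name in ols.params.index:
        scale = max(abs(ols.params[name]), 1.0)
        assert abs(res.estimate(name) - ols.params[name]) / scale < 1e-5


def test_missing_covariate_raises(cohort_table):
    with pytest.raises(KeyError, match="qrs_duration"):
        fit_ap_mixed_model(
            cohort_table, ModelSpec("APD90", fixed_effects=("qrs_duration",))
        )


def test_single_patient_grouping_rejected(cohort_table):
    one = cohort_table[cohort_table.patient_id == "P000"]
    with pytest.raises(ValueError, match="2 levels"):
        fit_ap_mixed_model(one, ModelSpec("APD90"))


def test_fibrosis_model_recovers_repair_effect():
    # section-level fibrosis with a known repaired-status effect
    rng = np.random.default_rng(3)
    n_pat, n_sec = 25, 8
    repaired = rng.binomial(1, 6 / 25, n_pat).astype(float)
    b = rng.normal(0, 4.0, n_pat)
    rows = []
    for i in range(n_pat):
        for s in range(n_sec):
            rows.append({
                "patient_id": f"P{i:03d}",
                "repair_status": repaired[i],
                "percent_fibrosis": 12.0 + 20.4 * repaired[i] + b[i]
                + rng.normal(0, 3.0),
            })
    table = pd.DataFrame(rows)
    res = fit_fibrosis_model(
        table, ModelSpec("percent_fibrosis", fixed_effects=("repair_status",))
    )
    est, se = res.estimate("repair_status"), float(res.params.loc["repair_status", "se"])
    assert abs(est - 20.4) < 2 * se + 1e-9


def test_logistic_recovery_and_errors():
    rng = np.random.default_rng(5)
    n = 1500
    x = rng.binomial(1, 0.5, n).astype(float)
    logit = -0.5 + 1.5 * x
    y = rng.binomial(1, 1 / (1 + np.exp(-logit))).astype(float)
    table = pd.DataFrame({"repair_status": x, "tissue_arrhythmia": y})
    out = fit_logistic(table, "tissue_arrhythmia", ["repair_status"])
    assert not out["separation"]
    est = out["coefficients"].loc["repair_status", "estimate"]
    se = out["coefficients"].loc["repair_status", "se"]
    assert abs(est - 1.5) < 2 * se

    with pytest.raises(ValueError, match="single-class"):
        fit_logistic(pd.DataFrame({"y": [0.0] * 10, "x": range(10)}), "y", ["x"])

    # perfectly separated construction
    sep = pd.DataFrame({"y": [0.0] * 10 + [1.0] * 10,
                        "x": [0.0] * 10 + [1.0] * 10})
    out = fit_logistic(sep, "y", ["x"])
    assert out["separation"]


def test_ttest_properties():
    rng = np.random.default_rng(6)
    same = pd.DataFrame({
        "arrhythmia_provenance": ["drug"] * 5 + ["spontaneous"] * 5,
        **{p: list(range(5)) * 2 for p in DEPENDENTS},
    })
    res = ttest_drug_vs_spontaneous(same)
    assert np.allclose(res["t"], 0.0, atol=1e-12)
    assert np.allclose(res["p"], 1.0)

    shifted = pd.DataFrame({
        "arrhythmia_provenance": ["drug"] * 20 + ["spontaneous"] * 20,
        **{p: np.concatenate([rng.normal(100, 1, 20), rng.normal(105, 1, 20)])
           for p in DEPENDENTS},
    })
    assert (ttest_drug_vs_spontaneous(shifted)["p"] < 0.001).all()

    tiny = pd.DataFrame({
        "arrhythmia_provenance": ["drug", "spontaneous", "spontaneous"],
        **{p: [1.0, 2.0, 3.0] for p in DEPENDENTS},
    })
    with pytest.raises(ValueError, match="observations per group"):
        ttest_drug_vs_spontaneous(tiny)


def test_render_results_table(cohort_table):
    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for dep in DEPENDENTS:
            results.append(fit_ap_mixed_model(cohort_table, ModelSpec(dep)))
    table = render_results_table(results)
    assert table.shape == (1 + len(COVARIATES), 2 * len(DEPENDENTS))
    txt = format_text_table(table)
    assert "Intercept" in txt and "APD90" in txt

    with pytest.warns(UserWarning, match="missing"):
        partial = render_results_table(results[:3])
    assert partial[("APD90", "estimate")].isna().all()
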