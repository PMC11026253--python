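"""Mixed-effects and regression analyses of the cohort feature table.

Per-property linear mixed-effects models with a per-patient random intercept
(REML by default, Wald p-values), the percent-fibrosis mixed model, binomial
logistic regressions for binary outcomes, and the two-sample t-test comparing
AP properties between tissue with drug-induced and spontaneous arrhythmias.

The reported "adjusted R²" is the OLS adjusted R² of the fixed-effects-only
fit — a deliberate convention choice, since adjusted R² has no unique
definition for mixed models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .synth.cohort import COVARIATES, DEPENDENTS

__all__ = [
    "ModelSpec",
    "AssociationResult",
    "ConvergenceFailure",
    "fit_ap_mixed_model",
    "fit_fibrosis_model",
    "fit_logistic",
    "ttest_drug_vs_spontaneous",
    "render_results_table",
    "format_text_table",
]

ALPHA = 0.05  # significance level used throughout (uncorrected)


class ConvergenceFailure(RuntimeError):
    """Raised when a model fit is singular or fails to converge."""


@dataclass
class ModelSpec:
    """Specification of one mixed model fit.

    ``p_value_method`` selects the reference distribution of the Wald
    statistic: ``"wald-t-bw"`` (default) uses a t distribution with
    between-within degrees of freedom — patient-level covariates are tested
    against the number of patients, within-patient covariates against the
    number of observations — which keeps small-sample type-I error near
    nominal; ``"wald-z"`` uses the asymptotic normal reference.
    """

    dependent: str
    fixed_effects: tuple = COVARIATES
    random_intercept: str = "patient_id"
    estimation: str = "REML"
    p_value_method: str = "wald-t-bw"

    def __post_init__(self) -> None:
        if self.estimation not in ("REML", "ML"):
            raise ValueError("estimation must be 'REML' or 'ML'")
        if self.p_value_method not in ("wald-t-bw", "wald-z"):
            raise ValueError("p_value_method must be 'wald-t-bw' or 'wald-z'")


@dataclass
class AssociationResult:
    """Fitted fixed effects, p-values, and model-level summaries."""

    dependent: str
    params: pd.DataFrame          # index: covariate; columns: estimate, se, p
    adjusted_r2: float
    n_obs: int
    n_groups: int
    converged: bool = True
    dropped: list = field(default_factory=list)
    method: str = "REML"

    def estimate(self, name: str) -> float:
        return float(self.params.loc[name, "estimate"])

    def p_value(self, name: str) -> float:
        return float(self.params.loc[name, "p"])


def _check_columns(table: pd.DataFrame, spec: ModelSpec) -> None:
    missing = [c for c in (spec.dependent, *spec.fixed_effects, spec.random_intercept)
               if c not in table.columns]
    if missing:
        raise KeyError(f"covariate(s) absent from table: {', '.join(missing)}")


def fit_ap_mixed_model(table: pd.DataFrame, spec: ModelSpec) -> AssociationResult:
    """Fit one linear mixed model with patient random intercept.

    Covariates that are constant in ``table`` are dropped with a warning and
    reported in ``result.dropped`` (their estimates are NaN).  A singular or
    non-converged fit raises :class:`ConvergenceFailure`.
    """
    _check_columns(table, spec)
    groups = table[spec.random_intercept]
    if groups.nunique() < 2:
        raise ValueError(
            f"random-effect grouping {spec.random_intercept!r} must have "
            f">= 2 levels, got {groups.nunique()}"
        )
    usable = [c for c in spec.fixed_effects if table[c].nunique() > 1]
    dropped = [c for c in spec.fixed_effects if c not in usable]
    if dropped:
        warnings.warn(
            f"dropping constant covariate(s): {', '.join(dropped)}", stacklevel=2
        )
    formula = f"{spec.dependent} ~ " + (" + ".join(usable) if usable else "1")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(formula, table, groups=groups)
            res = md.fit(reml=(spec.estimation == "REML"))
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise ConvergenceFailure(
            f"mixed model for {spec.dependent} failed: {exc}"
        ) from exc
    if not np.all(np.isfinite(res.params)):
        raise ConvergenceFailure(
            f"mixed model for {spec.dependent} produced non-finite estimates"
        )

    # between-within df partition: a covariate constant within every patient
    # is a between-patient effect
    g = int(groups.nunique())
    n = int(len(table))
    is_between = {
        c: bool((table.groupby(groups, observed=True)[c].nunique() <= 1).all())
        for c in usable
    }
    p_between = 1 + sum(is_between.values())       # intercept counts as between
    p_within = len(usable) - sum(is_between.values())
    df_between = max(g - p_between, 1)
    df_within = max(n - g - p_within, 1)

    rows = ["Intercept", *spec.fixed_effects]
    params = pd.DataFrame(
        index=pd.Index(rows, name="covariate"),
        columns=["estimate", "se", "p"],
        dtype=float,
    )
    for name in rows:
        if name in res.fe_params.index:
            est = res.fe_params[name]
            se = res.bse_fe[name]
            params.loc[name, "estimate"] = est
            params.loc[name, "se"] = se
            if spec.p_value_method == "wald-z" or se == 0:
                params.loc[name, "p"] = res.pvalues[name]
            else:
                df = df_between if is_between.get(name, True) else df_within
                params.loc[name, "p"] = 2.0 * stats.t.sf(abs(est / se), df)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ols = smf.ols(formula, table).fit()
    return AssociationResult(
        dependent=spec.dependent,
        params=params,
        adjusted_r2=float(ols.rsquared_adj),
        n_obs=int(res.nobs),
        n_groups=int(groups.nunique()),
        converged=bool(getattr(res, "converged", True)),
        dropped=dropped,
        method=spec.estimation,
    )


def fit_fibrosis_model(table: pd.DataFrame, spec: ModelSpec | None = None) -> AssociationResult:
    """Mixed model with percent-fibrosis as dependent variable.

    ``table`` should contain one row per section (or repeated measure) with
    the clinical covariates and — where used — AP properties measured at
    1 Hz pacing.  Patient remains the random effect.
    """
    if spec is None:
        spec = ModelSpec(dependent="percent_fibrosis")
    if spec.dependent != "percent_fibrosis":
        raise ValueError("fit_fibrosis_model expects dependent='percent_fibrosis'")
    return fit_ap_mixed_model(table, spec)


def fit_logistic(
    table: pd.DataFrame,
    dependent: str,
    covariates,
) -> dict:
    """Binomial logistic regression of a binary outcome on covariates.

    Returns a dict with a coefficient table (estimate, se, z, p) and a
    ``separation`` flag; under (quasi-)separation the model is refit with an
    L1 penalty and reported as penalised, without p-values.
    """
    missing = [c for c in (dependent, *covariates) if c not in table.columns]
    if missing:
        raise KeyError(f"column(s) absent from table: {', '.join(missing)}")
    y = table[dependent].astype(float)
    classes = set(np.unique(y))
    if classes - {0.0, 1.0}:
        raise ValueError(f"{dependent} must be binary 0/1")
    if len(classes) < 2:
        raise ValueError(f"single-class outcome: {dependent} has no variation")
    X = sm.add_constant(table[list(covariates)].astype(float), has_constant="add")

    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            warnings.simplefilter("ignore", category=FutureWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True) or np.any(
            np.abs(res.params) > 50
        ):
            separation = True
    except Exception:
        separation = True

    if separation:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit_regularized(alpha=1.0, disp=0)
        coefs = pd.DataFrame(
            {"estimate": res.params, "se": np.nan, "z": np.nan, "p": np.nan}
        )
    else:
        coefs = pd.DataFrame(
            {
                "estimate": res.params,
                "se": res.bse,
                "z": res.tvalues,
                "p": res.pvalues,
            }
        )
    coefs.index.name = "covariate"
    return {
        "dependent": dependent,
        "coefficients": coefs,
        "separation": separation,
        "n_obs": int(len(y)),
    }


def ttest_drug_vs_spontaneous(
    summaries: pd.DataFrame,
    group_col: str = "arrhythmia_provenance",
    properties=DEPENDENTS,
) -> pd.DataFrame:
    """Two-sided two-sample t-test per AP property between tissue with
    drug-induced and tissue with spontaneous arrhythmias.

    ``summaries`` holds per-location summary rows across all pacing
    frequencies with a two-level ``group_col``.  Raises when a group is
    empty or has a single observation.
    """
    levels = [g for g in summaries[group_col].dropna().unique()]
    if len(levels) != 2:
        raise ValueError(
            f"{group_col} must have exactly 2 groups, got {levels}"
        )
    a = summaries[summaries[group_col] == levels[0]]
    b = summaries[summaries[group_col] == levels[1]]
    rows = []
    for prop in properties:
        x = a[prop].dropna().to_numpy()
        y = b[prop].dropna().to_numpy()
        if len(x) < 2 or len(y) < 2:
            raise ValueError(
                f"need >= 2 observations per group for {prop}, "
                f"got {len(x)} and {len(y)}"
            )
        t, p = stats.ttest_ind(x, y)
        rows.append({"property": prop, "t": float(t), "p": float(p),
                     "n_a": len(x), "n_b": len(y)})
    return pd.DataFrame(rows).set_index("property")


def render_results_table(results) -> pd.DataFrame:
    """Assemble per-dependent mixed-model results into one wide table.

    Rows are the covariates in reporting order (intercept first), columns a
    MultiIndex of (dependent, estimate|p).  Dependents with a missing or
    failed fit are left blank with a warning.
    """
    by_dep = {r.dependent: r for r in results if r is not None}
    missing = [d for d in DEPENDENTS if d not in by_dep]
    if missing:
        warnings.warn(
            f"results missing for dependent(s): {', '.join(missing)}; "
            "rendering a partial table",
            stacklevel=2,
        )
    rows = ["Intercept", *COVARIATES]
    cols = pd.MultiIndex.from_product([DEPENDENTS, ["estimate", "p"]])
    out = pd.DataFrame(index=pd.Index(rows, name="covariate"), columns=cols,
                       dtype=float)
    for dep, r in by_dep.items():
        for name in rows:
            if name in r.params.index:
                out.loc[name, (dep, "estimate")] = r.params.loc[name, "estimate"]
                out.loc[name, (dep, "p")] = r.params.loc[name, "p"]
    return out


def format_text_table(table: pd.DataFrame, alpha: float = ALPHA) -> str:
    """Plain-text rendering with significance stars (strictly p < alpha)."""
    lines = []
    deps = sorted({c[0] for c in table.columns}, key=list(DEPENDENTS).index)
    header = f"{'covariate':<26}" + "".join(f"{d:>16}" for d in deps)
    lines.append(header)
    lines.append("-" * len(header))
    for name, row in table.iterrows():
        cells = []
        for d in deps:
            est, p = row.get((d, "estimate")), row.get((d, "p"))
            if pd.isna(est):
                cells.append(f"{'--':>16}")
            else:
                star = "*" if (pd.notna(p) and p < alpha) else " "
                ptxt = f"{p:>6.3f}" if pd.notna(p) else "     -"
                cells.append(f"{est:>9.2f}{star}{ptxt}")
        lines.append(f"{name:<26}" + "".join(cells))
    return "\n".join(lines)
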