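"""Participation models: univariate screens, logistic fits, model reduction
and parameter-recovery experiments.

Fixed-effect fits use maximum-likelihood logistic regression (statsmodels);
random-intercept fits use the Gauss-Hermite marginal-likelihood fitter in
:mod:`peernet.glmm`.  Inference is Wald throughout: odds ratios are
exponentiated coefficients with exp-transformed 95% confidence limits.

Model reduction mirrors manual backward elimination: the single least
significant removable term is dropped per iteration until every remaining
term is significant, respecting marginality (no main effect leaves while its
interaction remains; the Age x AgeObserved device travels as a pair).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import COVARIATES, covariate_frame
from .exceptions import ConfigurationError, StructuralError
from .glmm import GLMMResult, fit_logistic_random_intercept
from .simulate import SimConfig, simulate_study

Z975 = float(stats.norm.ppf(0.975))

AGE_PAIR = ("age", "age_observed")


@dataclass(frozen=True)
class ModelSpec:
    """A logistic model: outcome, main terms, interactions, optional random
    intercept grouping column."""

    outcome: str
    terms: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()
    random_intercept: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))
        object.__setattr__(
            self, "interactions", tuple(tuple(i) for i in self.interactions)
        )
        if "age" in self.terms and "age_observed" not in self.terms:
            raise ConfigurationError(
                "age may only enter as Age x AgeObserved together with the "
                "age_observed main effect"
            )

    def column_names(self) -> list[str]:
        return ["const", *self.terms, *(f"{a}:{b}" for a, b in self.interactions)]


@dataclass
class ModelFit:
    """Per-term estimates (log-odds, OR, Wald 95% CI, p) plus diagnostics."""

    spec: ModelSpec
    table: pd.DataFrame
    n: int
    loglik: float
    converged: bool
    method: str
    tau: float | None = None
    tau_se: float | None = None
    warnings: list[str] = field(default_factory=list)


def design_matrix(spec: ModelSpec, data: pd.DataFrame) -> pd.DataFrame:
    cols = {"const": np.ones(len(data))}
    for t in spec.terms:
        if t not in data.columns:
            raise StructuralError(f"model term '{t}' not in data")
        cols[t] = data[t].to_numpy(dtype=float)
    for a, b in spec.interactions:
        for t in (a, b):
            if t not in data.columns:
                raise StructuralError(f"interaction term '{t}' not in data")
        cols[f"{a}:{b}"] = (data[a] * data[b]).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=data.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        collinear = _collinear_columns(X.to_numpy(), list(X.columns))
        raise ConfigurationError(f"singular design matrix; collinear terms: {collinear}")
    return X


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns whose removal restores full rank (reported, not fixed)."""
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[j] for j in np.flatnonzero(diag < tol)]


def _wald_table(names, coef, se) -> pd.DataFrame:
    coef = np.asarray(coef, dtype=float)
    se = np.asarray(se, dtype=float)
    z = np.divide(coef, se, out=np.full_like(coef, np.nan), where=se > 0)
    p = 2 * stats.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):
        return pd.DataFrame(
            {
                "coef": coef,
                "se": se,
                "odds_ratio": np.exp(coef),
                "ci_low": np.exp(coef - Z975 * se),
                "ci_high": np.exp(coef + Z975 * se),
                "p": p,
            },
            index=pd.Index(names, name="term"),
        )


def fit_logistic(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Maximum-likelihood logistic regression with Wald inference.

    Complete separation is reported via ``ModelFit.warnings`` (the fit falls
    back to BFGS and flags the unstable estimates) rather than raised.
    """
    if spec.random_intercept is not None:
        raise ConfigurationError("spec has a random intercept; use fit_random_intercept")
    X = design_matrix(spec, data)
    y = data[spec.outcome].to_numpy(dtype=float)
    notes: list[str] = []
    model = sm.Logit(y, X.to_numpy())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, method="bfgs", maxiter=500)
        converged = False
        notes.append("complete separation detected; estimates are unstable")
    if np.abs(res.params).max() > 15:
        notes.append("very large coefficient magnitude; possible separation")
    table = _wald_table(X.columns, res.params, res.bse)
    return ModelFit(
        spec=spec,
        table=table,
        n=len(y),
        loglik=float(res.llf),
        converged=converged,
        method="ml-logistic",
        warnings=notes,
    )


def fit_random_intercept(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Random-intercept logistic fit grouped by ``spec.random_intercept``.

    A tau estimate at the zero boundary is valid output; the fixed effects
    then coincide with the plain logistic fit.
    """
    if spec.random_intercept is None:
        raise ConfigurationError("spec lacks a random_intercept grouping column")
    if spec.random_intercept not in data.columns:
        raise StructuralError(f"grouping column '{spec.random_intercept}' not in data")
    X = design_matrix(spec, data)
    y = data[spec.outcome].to_numpy(dtype=float)
    groups = data[spec.random_intercept].to_numpy()
    start = None
    try:
        fixed = fit_logistic(replace(spec, random_intercept=None), data)
        if fixed.converged:
            start = fixed.table["coef"].to_numpy()
    except Exception:
        pass
    res: GLMMResult = fit_logistic_random_intercept(
        X.to_numpy(), y, groups, names=list(X.columns), start_beta=start
    )
    table = _wald_table(res.names, res.beta, res.beta_se)
    return ModelFit(
        spec=spec,
        table=table,
        n=res.n,
        loglik=res.loglik,
        converged=res.converged,
        method="glmm-gauss-hermite",
        tau=res.tau,
        tau_se=res.tau_se,
    )


def fit(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    if spec.random_intercept is None:
        return fit_logistic(spec, data)
    return fit_random_intercept(spec, data)


# ---------------------------------------------------------------------------
# univariate screens


def univariate_tests(
    data: pd.DataFrame,
    outcome: str = "participated",
    continuous: tuple[str, ...] = (),
    categorical: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Two-group univariate screens of candidate predictors.

    Continuous variables: two-sided Student t-test (equal variances) on
    non-missing values, with per-group mean (SD) and missing counts.
    Categorical variables: chi-squared test without continuity correction on
    the category x outcome contingency table (missing values form their own
    reported category but are excluded from the test).
    """
    y = data[outcome]
    if y.isna().any():
        raise ConfigurationError("outcome contains missing values")
    g1, g0 = data[y == 1], data[y == 0]
    rows = []
    for var in continuous:
        a = pd.to_numeric(g1[var], errors="coerce").dropna()
        b = pd.to_numeric(g0[var], errors="coerce").dropna()
        row = {
            "variable": var,
            "type": "continuous",
            "mean_participated": float(a.mean()),
            "sd_participated": float(a.std(ddof=1)),
            "mean_declined": float(b.mean()),
            "sd_declined": float(b.std(ddof=1)),
            "n_missing": int(data[var].isna().sum()),
            "test": "t",
        }
        if a.nunique() <= 1 and b.nunique() <= 1 and (len(a) == 0 or len(b) == 0 or a.iloc[0] == b.iloc[0]):
            row.update(statistic=np.nan, p=np.nan, note="constant variable; test skipped")
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
            row.update(statistic=float(t), p=float(p), note="")
        rows.append(row)
    for var in categorical:
        tab = pd.crosstab(data[var], y)
        row = {
            "variable": var,
            "type": "categorical",
            "counts_participated": g1[var].value_counts(dropna=False).to_dict(),
            "counts_declined": g0[var].value_counts(dropna=False).to_dict(),
            "n_missing": int(data[var].isna().sum()),
            "test": "chi2",
        }
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            row.update(statistic=np.nan, p=np.nan, note="constant variable; test skipped")
        else:
            chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
            row.update(statistic=float(chi2), p=float(p), note="")
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# backward elimination


def _removal_units(spec: ModelSpec) -> list[dict]:
    """Removable units: interactions first-class; main effects only when free
    of remaining interactions; the age pair moves together."""
    units = []
    in_interaction = {t for pair in spec.interactions for t in pair}
    for a, b in spec.interactions:
        units.append({"kind": "interaction", "cols": [f"{a}:{b}"], "remove": (a, b)})
    age_unit_added = False
    for t in spec.terms:
        if t in in_interaction:
            continue
        if t in AGE_PAIR:
            if set(AGE_PAIR) <= set(spec.terms):
                if not age_unit_added:
                    units.append({"kind": "age-pair", "cols": list(AGE_PAIR), "remove": AGE_PAIR})
                    age_unit_added = True
                continue
        units.append({"kind": "main", "cols": [t], "remove": (t,)})
    return units


def reduce_model(
    spec: ModelSpec, data: pd.DataFrame, alpha: float = 0.05
) -> tuple[ModelSpec, list[dict], ModelFit]:
    """Backward elimination: drop the least significant removable unit per
    iteration until all remaining terms have p < alpha.

    A unit's p-value is its column's Wald p (for the age pair: the smaller of
    the two, so the pair survives if either member is significant).  Ties are
    broken by term order.  An empty (intercept-only) model is a legal
    terminus.  Returns (final spec, removal trace, final fit).
    """
    current = spec
    trace: list[dict] = []
    while True:
        result = fit(current, data)
        units = _removal_units(current)
        if not units:
            return current, trace, result
        pvals = []
        for u in units:
            pu = min(result.table.loc[c, "p"] for c in u["cols"])
            pvals.append(1.0 if np.isnan(pu) else pu)
        worst = int(np.argmax(pvals))
        if pvals[worst] < alpha:
            return current, trace, result
        unit = units[worst]
        if unit["kind"] == "interaction":
            a, b = unit["remove"]
            current = replace(
                current,
                interactions=tuple(
                    i for i in current.interactions if i != (a, b)
                ),
            )
        else:
            current = replace(
                current,
                terms=tuple(t for t in current.terms if t not in unit["remove"]),
            )
        trace.append({"removed": unit["cols"], "p": float(pvals[worst])})


# ---------------------------------------------------------------------------
# parameter recovery


def recovery_frame(study, use_true_exposures: bool = True) -> pd.DataFrame:
    """Model frame for one simulated study.

    With ``use_true_exposures`` the decision-time exposures recorded in the
    generating truth are used, making the sequential data-generating process
    and the fitted model coincide; otherwise exposures are recomputed
    observationally from the final outcomes (which reintroduces the
    within-hospital simultaneity the study design warns about).
    """
    truth = study.truth
    phys = study.physicians.set_index("physician_id")
    exp_df = truth.true_exposures
    if not use_true_exposures:
        from .exposure import build_exposure_table
        from .network import (
            attribute_physicians,
            binarize,
            build_encounter_matrix,
            project_shared_patients,
        )

        attr = attribute_physicians(study.billing)
        B = binarize(project_shared_patients(build_encounter_matrix(study.billing)), 0.0)
        steps = study.hospitals.set_index("hospital_id")["step"]
        y = phys["participated"].astype(float)
        obs = build_exposure_table(B, attr, y, steps)
        exp_df = obs.join(truth.true_exposures[["primary_hospital", "step"]], how="left")
    frame = covariate_frame(phys.loc[exp_df.index])
    frame["participated"] = phys.loc[exp_df.index, "participated"].astype(float)
    for col in exp_df.columns:
        frame[col] = exp_df[col].to_numpy()
    return frame


def recovery_spec(beta, include_within: bool, random_intercept: bool) -> ModelSpec:
    modifier = "shannon" if beta.interaction_var == "shannon" else "n_nonprimary"
    terms = list(COVARIATES) + ["shannon"]
    if include_within:
        terms.append("wy_wi")
    terms.append("wy_ac_t")
    if modifier not in terms:
        terms.append(modifier)
    return ModelSpec(
        outcome="participated",
        terms=tuple(terms),
        interactions=(("wy_ac_t", modifier),),
        random_intercept="primary_hospital" if random_intercept else None,
    )


def true_coefficient_map(beta) -> dict[str, float]:
    modifier = "shannon" if beta.interaction_var == "shannon" else "n_nonprimary"
    out = {"const": beta.intercept}
    out.update(beta.covariates())
    out["shannon"] = beta.shannon
    out["wy_wi"] = beta.within
    out["wy_ac_t"] = beta.across
    out[f"wy_ac_t:{modifier}"] = beta.across_interaction
    if modifier == "n_nonprimary":
        out["n_nonprimary"] = 0.0
    return out


def parameter_recovery(
    config: SimConfig,
    n_reps: int,
    seed: int,
    use_true_exposures: bool = True,
    include_within: bool | None = None,
    mixed: bool | None = None,
) -> pd.DataFrame:
    """Simulate-refit experiment: per-coefficient bias, RMSE and CI coverage.

    ``include_within`` defaults to the sequential-DGP flag
    (``use_true_exposures``): with decision-time exposures the within-hospital
    term is identified, whereas with observational exposures it is excluded by
    default, echoing the endogeneity argument of the study design.  The fit is
    mixed (random intercept by primary hospital) when the generating ``tau``
    is positive, fixed otherwise, unless ``mixed`` overrides.
    """
    if include_within is None:
        include_within = use_true_exposures
    if mixed is None:
        mixed = config.tau > 0
    spec = recovery_spec(config.beta, include_within, mixed)
    truth_map = true_coefficient_map(config.beta)
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_reps, dtype=np.uint32)
    records, ns = [], []
    for r in range(n_reps):
        study = simulate_study(replace(config, seed=int(rep_seeds[r]) % (2**31)))
        frame = recovery_frame(study, use_true_exposures=use_true_exposures)
        result = fit(spec, frame)
        ns.append(result.n)
        for term, row in result.table.iterrows():
            if term not in truth_map:
                continue
            true = truth_map[term]
            lo = row["coef"] - Z975 * row["se"]
            hi = row["coef"] + Z975 * row["se"]
            records.append(
                {
                    "rep": r,
                    "term": term,
                    "true": true,
                    "estimate": row["coef"],
                    "se": row["se"],
                    "covered": bool(lo <= true <= hi),
                }
            )
    df = pd.DataFrame(records)
    report = (
        df.groupby("term", sort=False)
        .agg(
            true=("true", "first"),
            mean_estimate=("estimate", "mean"),
            coverage=("covered", "mean"),
            n_reps=("rep", "count"),
        )
        .assign(
            bias=lambda d: d["mean_estimate"] - d["true"],
            rmse=lambda d: [
                float(np.sqrt(((df.loc[df.term == t, "estimate"] - df.loc[df.term == t, "true"]) ** 2).mean()))
                for t in d.index
            ],
        )
    )
    report.attrs["mean_n"] = float(np.mean(ns))
    return report
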