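"""Risk-factor analysis of the movement outcomes.

Four per-dog outcomes — daily distance (km), core and extended home
range (ha), and percent of recording time at the household — are
modelled against the questionnaire covariates with linear mixed models
carrying a random intercept for study site (REML).  Core HR enters as a
square root and extended HR on the log scale.  Following the study's
small-sample convention, associations are declared significant at
p <= 0.1, and the intracluster correlation coefficient
ICC = sigma_b^2 / (sigma_b^2 + sigma_w^2) summarises between-site
clustering.  Age is dichotomised (<1 vs >= 1 year) and sex/neuter status
is coded against an intact-male referent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger("roamrange")

P_SIGNIFICANT = 0.1

OUTCOMES = ("daily_distance_km", "core_hr_ha", "extended_hr_ha", "pct_time_household")
MODEL_OUTCOMES = {
    "daily_distance_km": "daily_distance_km",
    "core_hr_ha": "sqrt_core_hr",
    "extended_hr_ha": "log_extended_hr",
    "pct_time_household": "pct_time_household",
}


@dataclass
class MixedFitResult:
    """Fixed effects + variance components of one random-intercept fit."""

    outcome: str
    fixed_terms: tuple[str, ...]
    coefficients: pd.Series
    std_errors: pd.Series
    p_values: pd.Series
    term_p_values: dict[str, float]      # joint Wald p per model term
    sigma2_between: float
    sigma2_within: float
    icc: float
    n_obs: int
    n_groups: int
    converged: bool
    used_ols_fallback: bool = False
    significant_terms: tuple[str, ...] = ()


def prepare_outcomes(table: pd.DataFrame, corr_threshold: float = 0.7) -> pd.DataFrame:
    """Add transformed outcomes and run the collinearity screen.

    Adds ``sqrt_core_hr`` and ``log_extended_hr`` and a dichotomised
    ``age_ge1`` where ``age_class`` is present.  Pairwise Pearson
    correlations among the four outcomes are computed; pairs at
    ``|r| >= corr_threshold`` are flagged (attached as
    ``table.attrs["collinear_pairs"]``; the full matrix as
    ``table.attrs["outcome_correlations"]``).
    """
    out = table.copy()
    missing = [c for c in OUTCOMES if c not in out.columns]
    if missing:
        raise ValueError(f"analysis table missing outcomes {missing}")
    if out[list(OUTCOMES)].isna().any().any():
        raise ValueError("analysis table has missing outcome values")
    if (out["core_hr_ha"] < 0).any():
        raise ValueError("negative core HR cannot be square-root transformed")
    if (out["extended_hr_ha"] <= 0).any():
        raise ValueError("non-positive extended HR cannot be log transformed")
    out["sqrt_core_hr"] = np.sqrt(out["core_hr_ha"])
    out["log_extended_hr"] = np.log(out["extended_hr_ha"])
    if "age_class" in out.columns and "age_ge1" not in out.columns:
        out["age_ge1"] = (out["age_class"] != "<1 yr").astype(int)
    if "sex_status" in out.columns:
        out["sex_status"] = pd.Categorical(
            out["sex_status"],
            categories=["intact male", "castrated male", "intact female", "spayed female"],
        )

    corr = out[list(OUTCOMES)].corr(method="pearson")
    pairs = [
        (a, b, float(corr.loc[a, b]))
        for i, a in enumerate(OUTCOMES)
        for b in OUTCOMES[i + 1:]
        if abs(corr.loc[a, b]) >= corr_threshold
    ]
    out.attrs["outcome_correlations"] = corr
    out.attrs["collinear_pairs"] = pairs
    if pairs:
        logger.warning("collinear outcome pairs (|r| >= %.2f): %s", corr_threshold, pairs)
    else:
        logger.info("all outcome correlations below %.2f; outcomes retained separately",
                    corr_threshold)
    return out


def _term_columns(params: pd.Series, term: str) -> list[str]:
    """Design-matrix columns belonging to one formula term."""
    exact = [n for n in params.index if n == term]
    if exact:
        return exact
    return [n for n in params.index if n.startswith(f"{term}[")]


def fit_mixed_model(
    table: pd.DataFrame,
    outcome: str,
    fixed_terms: tuple[str, ...] = ("age_ge1", "sex_status"),
) -> MixedFitResult:
    """REML random-intercept fit of one outcome on the given fixed terms.

    ``outcome`` may be a raw outcome name (transformed automatically per
    the modelling convention) or any column already on the table.
    Categorical terms get a joint Wald p-value across their levels.  A
    boundary fit (sigma_b -> 0) is reported with sigma2_between = 0; a
    single-site table falls back to OLS with a warning.
    """
    col = MODEL_OUTCOMES.get(outcome, outcome)
    if col not in table.columns:
        raise ValueError(f"outcome column {col!r} not in table (run prepare_outcomes?)")
    for t in fixed_terms:
        if t not in table.columns:
            raise ValueError(f"fixed term {t!r} not in table")
    varying = tuple(t for t in fixed_terms if table[t].nunique() >= 2)
    dropped = set(fixed_terms) - set(varying)
    if dropped:
        logger.warning("dropping fixed terms without variation: %s", sorted(dropped))
    fixed_terms = varying
    if not fixed_terms:
        raise ValueError("no fixed term shows any variation")
    formula = f"{col} ~ " + " + ".join(fixed_terms)

    n_groups = table["site"].nunique() if "site" in table.columns else 1
    used_ols = n_groups < 2
    if used_ols:
        warnings.warn("fewer than 2 sites: falling back to ordinary least squares",
                      stacklevel=2)
        fit = smf.ols(formula, data=table).fit()
        s2b, s2w = 0.0, float(fit.mse_resid)
        converged = True
    else:
        model = smf.mixedlm(formula, data=table, groups=table["site"])
        fit = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # BFGS occasionally hits a singular profiled system on hard
            # draws; gradient-free optimizers are slower but robust
            for method in (None, "powell", "nm"):
                try:
                    kw = {} if method is None else {"method": method}
                    fit = model.fit(reml=True, **kw)
                    break
                except np.linalg.LinAlgError:
                    continue
        if fit is None:
            raise RuntimeError(f"mixed model failed to fit for {formula!r}")
        s2b = float(np.asarray(fit.cov_re)[0, 0])
        s2w = float(fit.scale)
        if s2b < 1e-10:  # boundary fit: random intercept vanishes
            s2b = 0.0
        converged = bool(fit.converged)

    params = fit.params.drop(labels=["Group Var"], errors="ignore")
    bse = fit.bse.reindex(params.index)
    pvals = fit.pvalues.reindex(params.index)

    term_p: dict[str, float] = {}
    for t in fixed_terms:
        cols = _term_columns(params, t)
        if len(cols) == 1:
            term_p[t] = float(pvals[cols[0]])
        elif cols:
            contrast = np.zeros((len(cols), len(fit.params)))
            names = list(fit.params.index)
            for r, c in enumerate(cols):
                contrast[r, names.index(c)] = 1.0
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                wt = fit.wald_test(contrast, scalar=True)
            term_p[t] = float(wt.pvalue)

    icc = s2b / (s2b + s2w) if (s2b + s2w) > 0 else float("nan")
    sig = tuple(t for t, p in term_p.items() if p <= P_SIGNIFICANT)
    return MixedFitResult(
        outcome=outcome,
        fixed_terms=tuple(fixed_terms),
        coefficients=params,
        std_errors=bse,
        p_values=pvals,
        term_p_values=term_p,
        sigma2_between=s2b,
        sigma2_within=s2w,
        icc=icc,
        n_obs=len(table),
        n_groups=n_groups,
        converged=converged,
        used_ols_fallback=used_ols,
        significant_terms=sig,
    )


def compute_icc(fit: MixedFitResult) -> float:
    """Between-site share of total variance, sigma_b^2/(sigma_b^2+sigma_w^2)."""
    total = fit.sigma2_between + fit.sigma2_within
    if total <= 0:
        logger.warning("both variance components are zero; ICC undefined")
        return float("nan")
    return fit.sigma2_between / total


def unconditional_tests(
    table: pd.DataFrame,
    covariates: tuple[str, ...] = ("age_class", "sex_status", "reported_time_outside",
                                   "fixes_per_hour", "recording_hours"),
    outcomes: tuple[str, ...] = OUTCOMES,
) -> pd.DataFrame:
    """Single-covariate mixed models for every covariate x outcome pair.

    Categorical covariates are tested jointly (Wald across levels) and
    summarised with per-level mean/SD/median of each raw outcome;
    continuous covariates report their slope p-value.  Covariates without
    variation are excluded (as happens to dog purpose and feeding
    frequency in a near-uniform cohort).
    """
    rows = []
    for cov in covariates:
        if cov not in table.columns:
            continue
        n_levels = table[cov].nunique()
        if n_levels < 2:
            logger.info("excluding %r: lack of variation", cov)
            rows.append({"covariate": cov, "status": "excluded (lack of variation)"})
            continue
        is_cat = not pd.api.types.is_numeric_dtype(table[cov])
        for outc in outcomes:
            fit = fit_mixed_model(table, outc, fixed_terms=(cov,))
            row = {
                "covariate": cov,
                "outcome": outc,
                "p_value": fit.term_p_values[cov],
                "status": "tested",
                "significant": fit.term_p_values[cov] <= P_SIGNIFICANT,
            }
            rows.append(row)
        if is_cat:
            for level, grp in table.groupby(cov, observed=True):
                if len(grp) == 0:
                    logger.warning("empty category %r of %r dropped", level, cov)
                    continue
                rows.append({
                    "covariate": cov, "level": str(level), "status": "summary",
                    "n": len(grp),
                    **{
                        f"{o}_{stat}": float(getattr(grp[o], fn)())
                        for o in outcomes
                        for stat, fn in (("mean", "mean"), ("sd", "std"), ("median", "median"))
                    },
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Influence diagnostics
# ---------------------------------------------------------------------------

@dataclass
class InfluenceReport:
    leave_one_site_out: pd.DataFrame
    sign_stable_terms: tuple[str, ...]
    outlier_dogs: tuple[str, ...] = ()


def influence_assessment(
    table: pd.DataFrame,
    outcome: str,
    fixed_terms: tuple[str, ...] = ("age_ge1", "sex_status"),
    z_threshold: float = 3.0,
) -> InfluenceReport:
    """Leave-one-site-out refits plus standardized-residual outlier flags.

    A coefficient is "sign stable" when its sign matches the full-model
    sign in every leave-one-site-out refit.
    """
    full = fit_mixed_model(table, outcome, fixed_terms)
    rows = []
    for site in sorted(table["site"].unique()):
        sub = table[table["site"] != site]
        refit = fit_mixed_model(sub, outcome, fixed_terms)
        for name, val in refit.coefficients.items():
            rows.append({"left_out_site": site, "coef": name, "estimate": float(val)})
    loso = pd.DataFrame(rows)
    stable = []
    for name, val in full.coefficients.items():
        ests = loso.loc[loso["coef"] == name, "estimate"]
        if len(ests) and (np.sign(ests) == np.sign(val)).all():
            stable.append(name)

    col = MODEL_OUTCOMES.get(outcome, outcome)
    resid = table[col] - _predict_fixed(full, table)
    z = (resid - resid.mean()) / resid.std(ddof=1)
    outliers = tuple(table.loc[np.abs(z) > z_threshold, "dog_id"].astype(str)) \
        if "dog_id" in table.columns else ()
    return InfluenceReport(
        leave_one_site_out=loso,
        sign_stable_terms=tuple(stable),
        outlier_dogs=outliers,
    )


def _predict_fixed(fit: MixedFitResult, table: pd.DataFrame) -> np.ndarray:
    """Fixed-effect prediction from a fitted result (no random effects)."""
    import patsy

    rhs = " + ".join(fit.fixed_terms)
    dm = patsy.dmatrix(rhs, table, return_type="dataframe")
    common = [c for c in dm.columns if c in fit.coefficients.index]
    return dm[common].to_numpy() @ fit.coefficients[common].to_numpy()
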