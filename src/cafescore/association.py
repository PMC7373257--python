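"""Quartile association models, trend and heterogeneity tests, FDR.

The reporting convention mirrors the two-model trick for skewed outcomes:
effects and confidence intervals come from models of the untransformed
outcome (so they read in natural units — percentage points, items,
minutes), while P values come from models of the rank-based
inverse-normalized outcome.  Binary outcomes use logistic regression with
Wald intervals on the log-odds scale, reported as odds ratios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import ndtri
from scipy.stats import norm, rankdata

CONTINUOUS_OUTCOMES = ["healthy_purchasing_score", "total_items", "food_items",
                       "beverage_items", "breakfast_time_median",
                       "lunch_time_median"]
BINARY_OUTCOMES = ["skips_breakfast", "skips_lunch", "skips_dinner",
                   "prepares_breakfast_home", "prepares_lunch_home",
                   "prepares_dinner_home"]
OUTCOME_FAMILIES = {**{o: "purchases" for o in CONTINUOUS_OUTCOMES},
                    **{o: "survey" for o in BINARY_OUTCOMES}}


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform: z = Φ⁻¹((rank − 0.5)/n).

    Ranks are averaged for ties; output order matches input order.
    """
    x = np.asarray(values, float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("inverse normal transform requires a 1-D vector, n >= 2")
    if np.isnan(x).any():
        raise ValueError("inverse normal transform does not accept missing values")
    if np.ptp(x) == 0:
        raise ValueError("inverse normal transform undefined for constant input")
    r = rankdata(x, method="average")
    return ndtri((r - 0.5) / len(x))


def seasonality_terms(date) -> tuple:
    """(sin θ, cos θ) with θ = 2π (day-of-year − 1) / 365.25."""
    doy = pd.Timestamp(date).dayofyear
    theta = 2.0 * np.pi * (doy - 1) / 365.25
    return float(np.sin(theta)), float(np.cos(theta))


def seasonality_columns(dates) -> pd.DataFrame:
    """Vectorized seasonality harmonics for a date series."""
    doy = pd.to_datetime(pd.Series(dates)).dt.dayofyear.to_numpy(float)
    theta = 2.0 * np.pi * (doy - 1) / 365.25
    return pd.DataFrame({"season_sin": np.sin(theta), "season_cos": np.cos(theta)})


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values, in input order.

    q_i = min over j >= i (in the ascending sort) of p_j · m / j, capped at 1.
    """
    p = np.asarray(p_values, float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if len(p) == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("P values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def heterogeneity_test(b_a: float, se_a: float, b_b: float, se_b: float) -> float:
    """Two-sided P for the difference of two stratified estimates.

    z = (b_a − b_b) / sqrt(se_a² + se_b²); for odds ratios the inputs must be
    on the log-odds scale.
    """
    if not (np.isfinite(b_a) and np.isfinite(b_b)):
        raise ValueError("heterogeneity test requires finite estimates")
    if se_a <= 0 or se_b <= 0:
        raise ValueError("heterogeneity test requires positive standard errors")
    z = (b_a - b_b) / np.hypot(se_a, se_b)
    return float(2.0 * norm.sf(abs(z)))


def _check_design(x: np.ndarray, names: list) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        bad = [names[j] for j in np.flatnonzero(diag < 1e-8 * max(diag.max(), 1.0))]
        raise ValueError(f"singular design matrix; collinear columns: {bad or names}")


def _complete_cases(data: pd.DataFrame, cols: list):
    sub = data[cols].apply(pd.to_numeric, errors="coerce")
    return sub.dropna()


def _prepare(data, outcome, covariates, quartile_col):
    cols = [outcome, quartile_col] + list(covariates)
    sub = _complete_cases(data, cols)
    y = sub[outcome].to_numpy(float)
    q = sub[quartile_col].to_numpy(int)
    xcov = sub[list(covariates)].to_numpy(float)
    return y, q, xcov, sub


def _require_n(n: int, n_params: int) -> None:
    if n < 10 * n_params:
        raise ValueError(
            f"insufficient complete cases: {n} rows for {n_params} parameters "
            "(need >= 10 per parameter)")


def _logit_fit(y, x, names):
    """Logistic fit tolerant of separation: returns (params, se, p, converged)."""
    _check_design(x, names)
    k = x.shape[1]
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, x).fit(disp=0, maxiter=100)
        params, bse, pvals = res.params, res.bse, res.pvalues
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception:
        return np.full(k, np.nan), np.full(k, np.nan), np.full(k, np.nan), False
    if not np.all(np.isfinite(bse)) or np.any(bse > 50):
        converged = False
    return params, bse, pvals, converged


def fit_quartile_model(data: pd.DataFrame, outcome: str, outcome_type: str,
                       covariates, quartile_col: str = "quartile") -> pd.DataFrame:
    """Adjusted Q2/Q3/Q4-vs-Q1 contrasts for one outcome and one score.

    Continuous outcomes are fit twice: on the untransformed outcome for the
    effect and 95% CI in natural units, and on the inverse-normalized outcome
    for the reported P.  Binary outcomes use one logistic fit; the effect is
    an odds ratio with a Wald 95% CI.  Rows flagged ``converged=False`` mark
    separation or non-convergence (undefined CI rather than silent failure).

    Returns a DataFrame with one row per contrast: contrast, n, effect,
    ci_low, ci_high, beta, se, p, converged.  ``beta``/``se`` are on the
    model scale (natural units, or log-odds for binary).
    """
    y, q, xcov, _ = _prepare(data, outcome, covariates, quartile_col)
    dummies = np.column_stack([(q == lev).astype(float) for lev in (2, 3, 4)])
    x = np.column_stack([np.ones(len(y)), dummies, xcov])
    names = ["intercept", "Q2", "Q3", "Q4"] + list(covariates)
    _require_n(len(y), x.shape[1])

    rows = []
    if outcome_type == "continuous":
        _check_design(x, names)
        nat = sm.OLS(y, x).fit()
        rint = sm.OLS(inverse_normal_transform(y), x).fit()
        ci = nat.conf_int(alpha=0.05)
        for i, contrast in enumerate(("Q2", "Q3", "Q4"), start=1):
            rows.append({"contrast": contrast, "n": int(len(y)),
                         "effect": nat.params[i], "ci_low": ci[i, 0],
                         "ci_high": ci[i, 1], "beta": nat.params[i],
                         "se": nat.bse[i], "p": rint.pvalues[i],
                         "converged": True})
    elif outcome_type == "binary":
        uniq = np.unique(y)
        if not np.isin(uniq, [0.0, 1.0]).all():
            raise ValueError(f"binary outcome '{outcome}' must be coded 0/1")
        params, bse, pvals, converged = _logit_fit(y, x, names)
        zc = norm.ppf(0.975)
        for i, contrast in enumerate(("Q2", "Q3", "Q4"), start=1):
            ok = converged and np.isfinite(bse[i])
            rows.append({"contrast": contrast, "n": int(len(y)),
                         "effect": np.exp(params[i]) if np.isfinite(params[i]) else np.nan,
                         "ci_low": np.exp(params[i] - zc * bse[i]) if ok else np.nan,
                         "ci_high": np.exp(params[i] + zc * bse[i]) if ok else np.nan,
                         "beta": params[i], "se": bse[i] if ok else np.nan,
                         "p": pvals[i] if ok else np.nan, "converged": ok})
    else:
        raise ValueError(f"unknown outcome type '{outcome_type}'")
    return pd.DataFrame(rows)


def trend_test(data: pd.DataFrame, outcome: str, outcome_type: str,
               covariates, quartile_col: str = "quartile") -> float:
    """P for trend: the quartile index (1-4) entered as one ordinal term.

    From the inverse-normalized model for continuous outcomes, the logistic
    model for binary ones.
    """
    y, q, xcov, _ = _prepare(data, outcome, covariates, quartile_col)
    x = np.column_stack([np.ones(len(y)), q.astype(float), xcov])
    names = ["intercept", "quartile_index"] + list(covariates)
    _require_n(len(y), x.shape[1])
    if outcome_type == "continuous":
        _check_design(x, names)
        res = sm.OLS(inverse_normal_transform(y), x).fit()
        return float(res.pvalues[1])
    _, _, pvals, converged = _logit_fit(y, x, names)
    return float(pvals[1]) if converged else float("nan")


def fit_continuous_score_model(data: pd.DataFrame, outcome: str,
                               outcome_type: str, covariates,
                               score_col: str = "standardized") -> pd.DataFrame:
    """Per-SD sensitivity fit: the standardized score as a continuous exposure."""
    cols = [outcome, score_col] + list(covariates)
    sub = _complete_cases(data, cols)
    y = sub[outcome].to_numpy(float)
    x = np.column_stack([np.ones(len(y)), sub[score_col].to_numpy(float),
                         sub[list(covariates)].to_numpy(float)])
    names = ["intercept", "score_per_sd"] + list(covariates)
    _require_n(len(y), x.shape[1])
    if outcome_type == "continuous":
        _check_design(x, names)
        nat = sm.OLS(y, x).fit()
        rint = sm.OLS(inverse_normal_transform(y), x).fit()
        ci = nat.conf_int(alpha=0.05)
        return pd.DataFrame([{"contrast": "per_SD", "n": int(len(y)),
                              "effect": nat.params[1], "ci_low": ci[1, 0],
                              "ci_high": ci[1, 1], "beta": nat.params[1],
                              "se": nat.bse[1], "p": rint.pvalues[1],
                              "converged": True}])
    params, bse, pvals, converged = _logit_fit(y, x, names)
    zc = norm.ppf(0.975)
    ok = converged and np.isfinite(bse[1])
    return pd.DataFrame([{"contrast": "per_SD", "n": int(len(y)),
                          "effect": np.exp(params[1]) if np.isfinite(params[1]) else np.nan,
                          "ci_low": np.exp(params[1] - zc * bse[1]) if ok else np.nan,
                          "ci_high": np.exp(params[1] + zc * bse[1]) if ok else np.nan,
                          "beta": params[1], "se": bse[1] if ok else np.nan,
                          "p": pvals[1] if ok else np.nan, "converged": ok}])


def build_model_covariates(covariates: pd.DataFrame, pcs: pd.DataFrame | None,
                           sensitivity: bool = False) -> pd.DataFrame:
    """Numeric model covariates from the raw covariate table.

    Primary set: age, female indicator, seasonality sine/cosine, ancestry
    PCs.  The sensitivity set adds job type, education, smoking, and physical
    activity (categoricals dummy-coded, first level dropped).
    """
    out = pd.DataFrame({"participant_id": covariates["participant_id"]})
    out["age"] = pd.to_numeric(covariates["age"])
    out["sex_female"] = (covariates["sex"].astype(str) == "female").astype(float)
    season = seasonality_columns(covariates["enrollment_date"])
    out["season_sin"] = season["season_sin"].to_numpy()
    out["season_cos"] = season["season_cos"].to_numpy()
    if pcs is not None and len(pcs.columns):
        pcs = pcs.reset_index()
        out = out.merge(pcs, on="participant_id", how="left")
    if sensitivity:
        for col in ("job_type", "education", "physical_activity"):
            if col in covariates.columns:
                dummies = pd.get_dummies(covariates[col].astype(str),
                                         prefix=col, drop_first=True, dtype=float)
                out = pd.concat([out, dummies], axis=1)
        if "current_smoker" in covariates.columns:
            out["current_smoker"] = pd.to_numeric(covariates["current_smoker"])
    return out


def run_full_analysis(score_sets: dict, phenotypes: pd.DataFrame,
                      covariates: pd.DataFrame, pcs: pd.DataFrame | None = None,
                      sensitivity: bool = False,
                      cns_pair: tuple = ("BMI_CNS", "BMI_nonCNS"),
                      outcomes: dict | None = None):
    """All scores × all outcomes: quartile contrasts, trend, per-SD fit,
    family-wise BH-FDR, and CNS/non-CNS heterogeneity.

    Parameters
    ----------
    score_sets : mapping score name -> ScoreSet
    outcomes : optional mapping outcome name -> {"continuous", "binary"};
        defaults to the full quality/quantity/timing + survey menu.

    Returns
    -------
    (results, log) : tidy results DataFrame (one row per score × outcome ×
    contrast) and a run log listing per-model sample sizes.
    """
    if outcomes is None:
        outcomes = {**{o: "continuous" for o in CONTINUOUS_OUTCOMES},
                    **{o: "binary" for o in BINARY_OUTCOMES}}
    pheno_ids = set(phenotypes["participant_id"])
    cov_ids = set(covariates["participant_id"])
    orphans = sorted(pheno_ids.symmetric_difference(cov_ids))
    if orphans:
        raise ValueError(f"participant IDs do not align across tables: {orphans[:5]}")

    model_cov = build_model_covariates(covariates, pcs, sensitivity=sensitivity)
    cov_names = [c for c in model_cov.columns if c != "participant_id"]
    base = phenotypes.merge(model_cov, on="participant_id", validate="1:1")

    all_rows, log = [], {"models": []}
    for score_name, ss in score_sets.items():
        sdf = pd.DataFrame({"participant_id": ss.samples,
                            "quartile": ss.quartile,
                            "standardized": ss.standardized})
        data = base.merge(sdf, on="participant_id", validate="1:1")
        for outcome, otype in outcomes.items():
            rows = fit_quartile_model(data, outcome, otype, cov_names)
            rows["p_trend"] = trend_test(data, outcome, otype, cov_names)
            per_sd = fit_continuous_score_model(data, outcome, otype, cov_names)
            per_sd["p_trend"] = np.nan
            rows = pd.concat([rows, per_sd], ignore_index=True)
            rows.insert(0, "score", score_name)
            rows.insert(1, "outcome", outcome)
            rows.insert(2, "outcome_type", otype)
            rows.insert(3, "family", OUTCOME_FAMILIES.get(outcome, "other"))
            all_rows.append(rows)
            log["models"].append({"score": score_name, "outcome": outcome,
                                  "n": int(rows["n"].iloc[0])})
    results = pd.concat(all_rows, ignore_index=True)

    # BH-FDR within each family over the primary quartile-contrast tests
    results["p_adj"] = np.nan
    primary = results["contrast"].isin(["Q2", "Q3", "Q4"]) & results["p"].notna()
    for fam in results.loc[primary, "family"].unique():
        mask = primary & (results["family"] == fam)
        results.loc[mask, "p_adj"] = bh_fdr(results.loc[mask, "p"].to_numpy())

    # CNS vs non-CNS heterogeneity from the stratified fits
    results["p_int"] = np.nan
    a, b = cns_pair
    if a in score_sets and b in score_sets:
        for outcome in outcomes:
            for contrast in ("Q2", "Q3", "Q4", "per_SD"):
                sel_a = ((results["score"] == a) & (results["outcome"] == outcome)
                         & (results["contrast"] == contrast))
                sel_b = ((results["score"] == b) & (results["outcome"] == outcome)
                         & (results["contrast"] == contrast))
                ra, rb = results.loc[sel_a], results.loc[sel_b]
                if len(ra) == 1 and len(rb) == 1:
                    ba, sa = float(ra["beta"].iloc[0]), float(ra["se"].iloc[0])
                    bb, sb = float(rb["beta"].iloc[0]), float(rb["se"].iloc[0])
                    if np.isfinite([ba, sa, bb, sb]).all() and sa > 0 and sb > 0:
                        p_int = heterogeneity_test(ba, sa, bb, sb)
                        results.loc[sel_a | sel_b, "p_int"] = p_int
    return results, log
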