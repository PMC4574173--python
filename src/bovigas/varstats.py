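"""Mixed-model variance components, repeatability and diurnal analysis.

The phenotype of interest (daily CH4, its intensities, or the CH4:CO2
ratio) is modelled with a random-intercept linear mixed model

    y_ij = mu + X beta + C_j + e_ij,   C_j ~ N(0, s2_cow), e_ij ~ N(0, s2_e)

fitted by REML (statsmodels MixedLM).  From the variance components we
report the between- and within-cow coefficients of variation relative to
the estimated mean,

    CV_bc = 100 sqrt(s2_cow) / mu_hat,   CV_wc = 100 sqrt(s2_e) / mu_hat,

the within-year repeatability R = s2_cow / (s2_cow + s2_e), the
between-year repeatability R2 from the two-year model with year, intake
and ECM as fixed effects, Pearson correlations of cow means across
years, an hour-of-day diurnal profile with 6-h interval contrasts, and
the levels-of-variation summary (CV at sample / visit / day / period
aggregation plus the herd precision 2 CV / sqrt(n)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "MixedModelSpec",
    "VarianceComponents",
    "fit_random_intercept",
    "stepwise_select",
    "cv_components",
    "repeatability",
    "between_year_repeatability",
    "pearson_between_years",
    "diurnal_profile",
    "interval_of_hour",
    "levels_of_variation",
    "herd_precision",
    "variance_report",
]

RESPONSES = ("ch4_l_day", "ch4_per_edmi", "ch4_per_ecm", "ratio")

_CATEGORICAL = {"parity", "year", "hour"}


class EstimationError(ValueError):
    """Raised when a model cannot be estimated on the supplied data."""


@dataclass(frozen=True)
class MixedModelSpec:
    """Specification of one random-intercept mixed model."""

    response: str
    fixed_effects: tuple[str, ...] = ()
    group: str = "cow_id"
    visit_count_re: bool = False   # extra variance component for AMS visit count
    reml: bool = True

    def formula(self) -> str:
        terms = ["1"]
        for f in self.fixed_effects:
            terms.append(f"C({f})" if f in _CATEGORICAL else f)
        return f"{self.response} ~ " + " + ".join(terms)


@dataclass
class VarianceComponents:
    """REML variance components and fixed-effect estimates of one fit."""

    sigma2_cow: float
    sigma2_resid: float
    mean_estimate: float           # marginal mean at average covariates
    fixed_effects: pd.DataFrame    # term, estimate, se, p
    converged: bool
    n_obs: int
    n_groups: int
    loglike: float = float("nan")
    aic: float = float("nan")
    spec: MixedModelSpec | None = None


def _within_group_ss(data: pd.DataFrame, response: str, group: str) -> float:
    dev = data.groupby(group)[response].transform(lambda s: s - s.mean())
    return float((dev ** 2).sum())


def fit_random_intercept(data: pd.DataFrame, spec: MixedModelSpec) -> VarianceComponents:
    """Fit the random-intercept model and extract variance components.

    The estimated mean is the average fixed-effect linear predictor over
    the observed covariate distribution, which reduces to the grand mean
    for an intercept-only model.  Exactly-degenerate data (zero
    within-group sum of squares, intercept-only model) sits on the
    boundary of the likelihood where numerical optimisers stall; there
    the analytic REML limit is returned instead: s2_e = 0 and s2_cow the
    ddof-1 variance of the group means.
    """
    df = data.dropna(subset=[spec.response, spec.group, *spec.fixed_effects]).copy()
    groups = df[spec.group]
    if groups.nunique() < 2:
        raise EstimationError("need at least two groups (cows)")
    if not (df.groupby(spec.group).size() >= 2).any():
        raise EstimationError("need repeated observations within at least one group")

    if not spec.fixed_effects and _within_group_ss(df, spec.response, spec.group) == 0.0:
        means = df.groupby(spec.group)[spec.response].mean()
        mu = float(df[spec.response].mean())
        fe = pd.DataFrame({"term": ["Intercept"], "estimate": [mu], "se": [np.nan], "p": [np.nan]})
        return VarianceComponents(
            sigma2_cow=float(means.var(ddof=1)), sigma2_resid=0.0, mean_estimate=mu,
            fixed_effects=fe, converged=True, n_obs=len(df), n_groups=int(groups.nunique()),
            spec=spec,
        )

    vc_formula = {"visits": "0 + C(n_visits)"} if spec.visit_count_re else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(spec.formula(), df, groups=df[spec.group], vc_formula=vc_formula)
        # gradient methods occasionally stall short of the REML optimum;
        # keep the best of a gradient and a derivative-free fit
        candidates = []
        last_exc: Exception | None = None
        for method in (None, "powell", "nm"):
            try:
                fit = model.fit(reml=spec.reml) if method is None else model.fit(
                    reml=spec.reml, method=method
                )
                if np.isfinite(fit.llf):
                    candidates.append(fit)
                if len(candidates) == 2:
                    break
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
        result = max(candidates, key=lambda f: f.llf) if candidates else None
    if result is None:
        # optimiser failed at the s2_cow = 0 boundary: report the OLS limit
        ols = smf.ols(spec.formula(), df).fit()
        warnings.warn(f"mixed model optimiser failed ({last_exc}); "
                      "reporting the zero-cow-variance boundary fit")
        fe = pd.DataFrame({
            "term": list(ols.params.index), "estimate": ols.params.to_numpy(),
            "se": ols.bse.to_numpy(), "p": ols.pvalues.to_numpy(),
        })
        return VarianceComponents(
            sigma2_cow=0.0, sigma2_resid=float(ols.mse_resid),
            mean_estimate=float(ols.fittedvalues.mean()), fixed_effects=fe,
            converged=False, n_obs=len(df), n_groups=int(groups.nunique()),
            loglike=float(ols.llf), aic=float(ols.aic), spec=spec,
        )
    sigma2_cow = float(np.asarray(result.cov_re)[0, 0])
    sigma2_resid = float(result.scale)
    if not np.all(np.isfinite([sigma2_cow, sigma2_resid, *result.fe_params])):
        raise EstimationError("mixed model did not converge (non-finite estimates)")
    if not result.converged:
        # boundary fits (s2_cow ~ 0) report usable estimates with a flag
        warnings.warn("mixed model optimiser reported non-convergence; "
                      "estimates are likely on the variance boundary")
    if sigma2_cow < 1e-10 * max(sigma2_resid, 1.0):
        warnings.warn("singular fit: cow variance component is ~0")
    fe_names = list(result.fe_params.index)
    # marginal mean: fixed-effect prediction averaged over observed covariates
    mu_hat = float(np.mean(model.exog @ result.fe_params.to_numpy()))
    fe = pd.DataFrame({
        "term": fe_names,
        "estimate": result.fe_params.to_numpy(),
        "se": result.bse_fe.to_numpy(),
        "p": result.pvalues[fe_names].to_numpy(),
    })
    return VarianceComponents(
        sigma2_cow=sigma2_cow, sigma2_resid=sigma2_resid, mean_estimate=mu_hat,
        fixed_effects=fe, converged=bool(result.converged), n_obs=len(df),
        n_groups=int(groups.nunique()), loglike=float(result.llf),
        aic=float(getattr(result, "aic", np.nan)), spec=spec,
    )


def _term_pvalues(vc: VarianceComponents, fixed_effects: Sequence[str]) -> dict[str, float]:
    """Worst (largest) Wald p per model term, pooling categorical levels."""
    out: dict[str, float] = {}
    for f in fixed_effects:
        key = f"C({f})" if f in _CATEGORICAL else f
        rows = vc.fixed_effects[vc.fixed_effects["term"].str.startswith(key)]
        if not rows.empty:
            out[f] = float(rows["p"].min())  # min p of the term's coefficients
    return out


def stepwise_select(
    data: pd.DataFrame,
    full_spec: MixedModelSpec,
    alpha: float = 0.05,
) -> tuple[MixedModelSpec, list[dict]]:
    """Backward elimination of non-significant fixed effects.

    Refits (maximum likelihood, so nested fits are comparable) after each
    drop, removing the least significant effect with p > alpha one at a
    time; the AIC trail is returned as the step log.  The cow random
    intercept is never dropped; an optional visit-count component is
    tested last by a boundary likelihood-ratio test (50:50 chi2 mixture).
    Degenerate data yields the intercept-only model rather than an error.
    """
    fixed = list(full_spec.fixed_effects)
    log: list[dict] = []
    while True:
        spec = MixedModelSpec(full_spec.response, tuple(fixed), full_spec.group,
                              full_spec.visit_count_re, reml=False)
        vc = fit_random_intercept(data, spec)
        pvals = _term_pvalues(vc, fixed)
        log.append({"fixed_effects": tuple(fixed), "aic": vc.aic, "pvalues": dict(pvals)})
        if not fixed:
            break
        worst = max(pvals, key=pvals.get) if pvals else None
        if worst is None or pvals[worst] <= alpha:
            break
        fixed.remove(worst)

    visit_re = full_spec.visit_count_re
    if visit_re and "n_visits" in data.columns:
        with_re = fit_random_intercept(
            data, MixedModelSpec(full_spec.response, tuple(fixed), full_spec.group, True, reml=False)
        )
        without = fit_random_intercept(
            data, MixedModelSpec(full_spec.response, tuple(fixed), full_spec.group, False, reml=False)
        )
        lr = max(0.0, 2.0 * (with_re.loglike - without.loglike))
        p_re = 0.5 * sps.chi2.sf(lr, 1) + (0.5 if lr == 0 else 0.0)
        log.append({"visit_count_re_lrt": lr, "p": float(p_re)})
        if p_re > alpha:
            visit_re = False
    final = MixedModelSpec(full_spec.response, tuple(fixed), full_spec.group, visit_re, reml=True)
    return final, log


def cv_components(vc: VarianceComponents) -> tuple[float, float]:
    """Between- and within-cow CVs (%) relative to the estimated mean."""
    if not vc.mean_estimate > 0:
        raise EstimationError("estimated mean must be > 0 for CVs")
    cv_bc = 100.0 * np.sqrt(vc.sigma2_cow) / vc.mean_estimate
    cv_wc = 100.0 * np.sqrt(vc.sigma2_resid) / vc.mean_estimate
    return float(cv_bc), float(cv_wc)


def repeatability(vc: VarianceComponents, n_aggregated: int = 1) -> float:
    """R = s2_cow / (s2_cow + s2_e); NaN when both components vanish.

    ``n_aggregated`` > 1 gives the repeatability of an n-day *mean*
    phenotype (residual variance shrunk by n), the alternative reading
    under which published repeatabilities of averaged emissions exceed
    the day-level ratio of variance components.
    """
    if n_aggregated < 1:
        raise EstimationError("n_aggregated must be >= 1")
    resid = vc.sigma2_resid / n_aggregated
    total = vc.sigma2_cow + resid
    if total <= 0:
        return float("nan")
    return float(vc.sigma2_cow / total)


def between_year_repeatability(
    phenotypes: pd.DataFrame,
    response: str = "ch4_l_day",
    mode: Literal["cow-random", "year-random"] = "cow-random",
    fixed_effects: tuple[str, ...] = ("year", "edmi_kg_day", "ecm_kg_day", "parity"),
) -> tuple[float, VarianceComponents]:
    """Between-year repeatability R2 from the two-year model.

    Daily phenotypes are first collapsed to cow-year period means — the
    model is indexed by year and cow, one observation per cow per year.
    Default ('cow-random'): cow is the random intercept, year enters as a
    fixed effect alongside EDMI, ECM and parity, and
    R2 = s2_cow / (s2_cow + s2_e), i.e. the share of variance carried
    across years by the animal.  The literal alternative reading
    ('year-random') instead uses the year as the grouping factor.
    """
    if phenotypes["year"].nunique() < 2:
        raise EstimationError("between-year repeatability needs both years")
    agg = {response: (response, "mean")}
    for cov in fixed_effects:
        if cov != "year" and cov in phenotypes.columns:
            agg[cov] = (cov, "first" if phenotypes[cov].dtype == object else "mean")
    phenotypes = phenotypes.groupby(["cow_id", "year"], as_index=False).agg(**agg)
    if mode == "cow-random":
        spec = MixedModelSpec(response, tuple(fixed_effects), group="cow_id")
    else:
        fe = tuple(f for f in fixed_effects if f != "year")
        spec = MixedModelSpec(response, fe, group="year")
    vc = fit_random_intercept(phenotypes, spec)
    return repeatability(vc), vc


def pearson_between_years(
    phenotypes: pd.DataFrame,
    value: str = "ch4_l_day",
) -> tuple[float, float, int]:
    """Pearson r (and two-sided p) of matched cow means across two years.

    ``phenotypes`` must hold cow_id, year and the value column; rows are
    averaged to cow-year means, and cows present in both years are
    matched.  Pass an ECM-standardized column to get the adjusted
    correlation.
    """
    means = phenotypes.groupby(["cow_id", "year"], as_index=False)[value].mean()
    wide = means.pivot(index="cow_id", columns="year", values=value).dropna()
    if len(wide) < 3:
        raise EstimationError("need at least 3 cows present in both years")
    y1, y2 = wide.iloc[:, 0], wide.iloc[:, 1]
    r, p = sps.pearsonr(y1, y2)
    return float(r), float(p), int(len(wide))


# ---------------------------------------------------------------------------
# diurnal profile

_INTERVALS = (("night", 0, 5), ("morning", 6, 11), ("afternoon", 12, 17), ("evening", 18, 23))


def interval_of_hour(hour: int) -> str:
    """Map an hour of day to its 6-h interval (night 0000-0600, etc.)."""
    for name, lo, hi in _INTERVALS:
        if lo <= hour <= hi:
            return name
    raise ValueError(f"hour {hour} outside 0-23")


def diurnal_profile(
    hourly: pd.DataFrame,
    response: str = "ch4_l_h",
    covariates: tuple[str, ...] = ("edmi_kg_day", "ecm_kg_day", "parity"),
    hour_col: str = "hour_of_day",
) -> dict:
    """Hour-of-day adjusted means and 6-h interval contrasts.

    Fits ``response ~ C(hour) + covariates`` with a cow random intercept;
    adjusted hourly means are the fixed-effect predictions at the average
    covariate values, with delta-method standard errors.  Hours are then
    aggregated into the night / morning / afternoon / evening intervals
    and all pairwise interval differences are Wald-tested.  Hours with no
    observations are reported as missing and excluded from contrasts.
    """
    df = hourly.dropna(subset=[response, hour_col, "cow_id", *covariates]).copy()
    df["hour"] = df[hour_col].astype(int)
    covs = tuple(c for c in covariates if df[c].nunique() > 1)
    spec = MixedModelSpec(response, ("hour",) + covs, group="cow_id")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(spec.formula(), df, groups=df["cow_id"])
        result = None
        last_exc: Exception | None = None
        for method in (None, "powell", "nm"):
            try:
                result = model.fit(reml=True) if method is None else model.fit(
                    reml=True, method=method
                )
                break
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
        if result is None:
            raise EstimationError(f"diurnal mixed model failed: {last_exc}")
    exog = np.asarray(model.exog)
    names = list(model.exog_names)
    col_means = exog.mean(axis=0)
    hour_cols = {int(n.split("T.")[1].rstrip("]")): i for i, n in enumerate(names)
                 if n.startswith("C(hour)")}
    hours_present = sorted(df["hour"].unique())
    fe = result.fe_params.to_numpy()
    cov_fe = np.asarray(result.cov_params())[: len(fe), : len(fe)]

    design_rows: dict[int, np.ndarray] = {}
    rows = []
    for h in range(24):
        if h not in hours_present:
            rows.append({"hour": h, "adjusted_mean": np.nan, "se": np.nan,
                         "interval": interval_of_hour(h), "n": 0})
            continue
        m = col_means.copy()
        for hh, i in hour_cols.items():
            m[i] = 1.0 if hh == h else 0.0
        design_rows[h] = m
        rows.append({
            "hour": h,
            "adjusted_mean": float(m @ fe),
            "se": float(np.sqrt(m @ cov_fe @ m)),
            "interval": interval_of_hour(h),
            "n": int((df["hour"] == h).sum()),
        })
    hourly_table = pd.DataFrame(rows)

    interval_rows = []
    interval_L: dict[str, np.ndarray] = {}
    for name, lo, hi in _INTERVALS:
        hs = [h for h in range(lo, hi + 1) if h in design_rows]
        if not hs:
            continue
        L = np.mean([design_rows[h] for h in hs], axis=0)
        interval_L[name] = L
        interval_rows.append({
            "interval": name,
            "adjusted_mean": float(L @ fe),
            "se": float(np.sqrt(L @ cov_fe @ L)),
            "n_hours": len(hs),
        })
    interval_table = pd.DataFrame(interval_rows)

    contrasts = []
    labels = list(interval_L)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            L = interval_L[labels[i]] - interval_L[labels[j]]
            est = float(L @ fe)
            se = float(np.sqrt(L @ cov_fe @ L))
            z = est / se if se > 0 else np.nan
            contrasts.append({
                "contrast": f"{labels[i]} - {labels[j]}",
                "estimate": est, "se": se,
                "p": float(2 * sps.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
            })
    return {
        "hourly": hourly_table,
        "intervals": interval_table,
        "contrasts": pd.DataFrame(contrasts),
        "model": result,
    }


# ---------------------------------------------------------------------------
# levels of variation

def herd_precision(cv_pct: float, n_cows: int) -> float:
    """Herd-level precision (%) of the mean: 2 CV / sqrt(n_cows)."""
    if n_cows < 1:
        raise EstimationError("n_cows must be >= 1")
    return float(2.0 * cv_pct / np.sqrt(n_cows))


def levels_of_variation(ratios: Mapping[str, pd.DataFrame], value: str = "ratio") -> dict:
    """CV of the pooled data at each aggregation level, plus precision.

    ``ratios`` maps level name (sample/visit/day/period) to its table;
    the CV at each level is sd/mean (ddof=1, in %) over all units pooled
    across cows — at the period level, over the cow period means.  The
    herd precision is 2 CV_period / sqrt(n_cows), the %-half-width of the
    95% interval of the herd mean.
    """
    rows = []
    for level in ("sample", "visit", "day", "period"):
        if level not in ratios:
            continue
        x = ratios[level][value].dropna().to_numpy(dtype=float)
        if len(x) < 2:
            raise EstimationError(f"CV undefined at level '{level}' (fewer than 2 units)")
        rows.append({
            "level": level,
            "cv_pct": float(100.0 * x.std(ddof=1) / x.mean()),
            "n_units": int(len(x)),
        })
    table = pd.DataFrame(rows)
    precision = np.nan
    if "period" in ratios:
        n_cows = len(ratios["period"])
        cv_period = float(table.loc[table["level"] == "period", "cv_pct"].iloc[0])
        precision = herd_precision(cv_period, n_cows)
    return {"cv_by_level": table, "precision_pct": precision}


# ---------------------------------------------------------------------------
# per-year report assembly

def variance_report(
    phenotypes: pd.DataFrame,
    responses: Sequence[str] = RESPONSES,
    fixed_effects: tuple[str, ...] = ("edmi_kg_day", "ecm_kg_day", "parity"),
    alpha: float = 0.05,
    r2_mode: Literal["cow-random", "year-random"] = "cow-random",
    stepwise: bool = True,
) -> pd.DataFrame:
    """Mean, CV_bc, CV_wc, R per response and year, plus R2 across years.

    ``phenotypes`` is the daily phenotype table with a ``year`` column.
    Fixed effects are pruned by backward elimination (at ``alpha``) when
    ``stepwise`` is set, then the final model is refitted by REML.
    """
    out = []
    years = sorted(phenotypes["year"].unique())
    for response in responses:
        r2 = np.nan
        if len(years) >= 2:
            try:
                r2, _ = between_year_repeatability(phenotypes, response, mode=r2_mode)
            except EstimationError:
                r2 = np.nan
        for year in years:
            sub = phenotypes[phenotypes["year"] == year]
            fe = tuple(f for f in fixed_effects if f in sub.columns and sub[f].nunique() > 1)
            spec = MixedModelSpec(response, fe)
            if stepwise and fe:
                spec, _ = stepwise_select(sub, MixedModelSpec(response, fe, reml=False), alpha)
            vc = fit_random_intercept(sub, spec)
            cv_bc, cv_wc = cv_components(vc)
            out.append({
                "response": response, "year": year, "mean": vc.mean_estimate,
                "cv_bc": cv_bc, "cv_wc": cv_wc, "r_within": repeatability(vc),
                "r_between_years": r2, "n_cows": vc.n_groups, "n_obs": vc.n_obs,
                "fixed_effects": "+".join(vc.spec.fixed_effects) if vc.spec else "",
            })
    return pd.DataFrame(out)
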