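"""Linear mixed-effects models of longitudinal network cortical thinning.

The primary model regresses time-varying DMN composite thickness on the full
crossing of baseline DMN connectivity (FC), continuous amyloid burden (PiB
DVR), and time, plus demographic covariates crossed with time, with a
correlated random intercept and slope per subject:

    thickness ~ FC * PiB * time + (age + sex + education) * time
                + (time | subject)

Wilkinson-style crossing expands to 14 fixed effects (intercept; FC; PiB;
time; FC:PiB; FC:time; PiB:time; FC:PiB:time; age; sex; education; age:time;
sex:time; education:time).  The three-way FC:PiB:time term is the primary
quantity of interest.  Stratified fits drop every PiB term within an amyloid
group; augmented fits add FPCN connectivity, time-varying FPCN composite
thickness, and/or inferior-temporal tau terms to probe specificity.

Inference convention: t statistics are each fixed effect's estimate over its
standard error, referred to a Student t distribution with residual degrees
of freedom = observations - fixed effects; standardized effect sizes are
recovered from t as d = 2t/sqrt(df).  Continuous predictors are demeaned over
the whole analysis sample before fitting; no multiple-comparison correction
is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ModelFit",
    "GroupComparison",
    "demean",
    "prepare_model_table",
    "build_design",
    "fit_lme",
    "fit_primary_model",
    "fit_stratified_model",
    "fit_augmented_model",
    "effect_size_from_t",
    "pooled_two_sample_t",
    "chi_square_2x2",
]

#: extra term blocks accepted by :func:`fit_augmented_model`
EXTRA_TERMS = {
    "fpcn_fc": ["fpcn_fc", "fpcn_fc:time"],
    "fpcn_ct": ["fpcn_ct"],
    "it_tau": ["it_tau", "it_tau:time"],
}


@dataclass
class ModelFit:
    """Fixed-effect inference plus variance components for one LME fit."""

    params: pd.DataFrame  # index: term; columns: estimate, se, tstat, df, pvalue, cohens_d
    cov_re: pd.DataFrame
    residual_var: float
    converged: bool
    singular_re: bool
    n_obs: int
    n_subjects: int
    primary_term: str

    @property
    def primary(self) -> pd.Series:
        return self.params.loc[self.primary_term]

    def term(self, name: str) -> pd.Series:
        return self.params.loc[name]


@dataclass
class GroupComparison:
    """A two-group demographic comparison (t test or chi-square)."""

    variable: str
    statistic: float
    df: float
    pvalue: float
    detail: dict = field(default_factory=dict)


def demean(values) -> np.ndarray:
    """Subtract the full-sample mean (idempotent; NaNs propagate)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 1:
        raise ValueError("need at least one value to demean")
    out = arr - arr.mean()
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def prepare_model_table(
    table: pd.DataFrame,
    fc_col: str = "fc_true",
    pib_col: str = "pib_dvr",
    extra_cols: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Standardize a longitudinal table for modelling.

    Produces columns ``fc`` and ``pib`` (and any requested extras) demeaned
    over the whole sample, centers age and education, and leaves time in
    years from each subject's first visit.  Rows with missing required
    values are dropped listwise.
    """
    df = table.copy()
    required = ["subject", "time", "thickness", fc_col, pib_col, "age", "sex", "education"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"longitudinal table is missing columns: {missing}")
    before = len(df)
    df = df.dropna(subset=required + [c for c in extra_cols if c in df.columns])
    if len(df) < before:
        warnings.warn(f"dropped {before - len(df)} rows with missing values", stacklevel=2)
    df["time"] = df["time"] - df.groupby("subject")["time"].transform("min")
    df["fc"] = demean(df[fc_col].to_numpy())
    df["pib"] = demean(df[pib_col].to_numpy())
    df["age"] = demean(df["age"].to_numpy())
    df["education"] = demean(df["education"].to_numpy())
    for c in extra_cols:
        if c not in df.columns:
            raise ValueError(f"requested extra column {c!r} not in table")
        df[c] = demean(df[c].to_numpy())
    return df


def build_design(
    table: pd.DataFrame, include_pib: bool = True, extras: tuple[str, ...] = ()
) -> pd.DataFrame:
    """Fixed-effect design matrix with named columns.

    ``include_pib=False`` drops the four PiB terms (stratified models);
    ``extras`` adds term blocks from :data:`EXTRA_TERMS`.
    """
    t = table["time"]
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(table))}
    cols["fc"] = table["fc"].to_numpy()
    if include_pib:
        cols["pib"] = table["pib"].to_numpy()
    cols["time"] = t.to_numpy()
    if include_pib:
        cols["fc:pib"] = (table["fc"] * table["pib"]).to_numpy()
    cols["fc:time"] = (table["fc"] * t).to_numpy()
    if include_pib:
        cols["pib:time"] = (table["pib"] * t).to_numpy()
        cols["fc:pib:time"] = (table["fc"] * table["pib"] * t).to_numpy()
    for c in ("age", "sex", "education"):
        cols[c] = table[c].to_numpy()
    for c in ("age", "sex", "education"):
        cols[f"{c}:time"] = (table[c] * t).to_numpy()
    for extra in extras:
        if extra not in EXTRA_TERMS:
            raise ValueError(f"unknown extra term block {extra!r}")
        for term in EXTRA_TERMS[extra]:
            base = term.split(":")[0]
            if base not in table.columns:
                raise ValueError(f"extra column {base!r} not present in table")
            cols[term] = (
                (table[base] * t).to_numpy() if term.endswith(":time") else table[base].to_numpy()
            )
    return pd.DataFrame(cols, index=table.index)


def fit_lme(
    table: pd.DataFrame,
    design: pd.DataFrame,
    primary_term: str,
    reml: bool = True,
) -> ModelFit:
    """Fit the LME with correlated random intercept + slope per subject.

    t statistics are referred to Student t with residual df = n - p; Cohen's
    d per term is 2t/sqrt(df).  Non-convergence raises; a singular
    random-effects covariance is flagged (with a warning) but returned.
    """
    endog = table["thickness"].to_numpy()
    groups = table["subject"].to_numpy()
    exog_re = np.column_stack([np.ones(len(table)), table["time"].to_numpy()])
    model = MixedLM(endog, design.to_numpy(), groups=groups, exog_re=exog_re)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        result = None
        for method in ("lbfgs", "cg", "powell"):
            try:
                result = model.fit(reml=reml, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if result.converged:
                break
    if result is None or not result.converged:
        raise RuntimeError(
            "mixed-model optimizer failed to converge "
            f"(methods tried: lbfgs, cg, powell; n={len(table)})"
        )

    n, p = len(table), design.shape[1]
    df_resid = n - p
    est = np.asarray(result.fe_params, dtype=float)
    se = np.asarray(result.bse_fe, dtype=float)
    tval = est / se
    pval = 2.0 * stats.t.sf(np.abs(tval), df_resid)
    d = 2.0 * tval / np.sqrt(df_resid)
    params = pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "tstat": tval,
            "df": float(df_resid),
            "pvalue": pval,
            "cohens_d": d,
        },
        index=list(design.columns),
    )
    cov_re = pd.DataFrame(
        np.asarray(result.cov_re), index=["intercept", "time"], columns=["intercept", "time"]
    )
    eig = np.linalg.eigvalsh(cov_re.to_numpy())
    singular = bool(eig.min() < 1e-10 * max(eig.max(), 1e-300))
    if singular:
        warnings.warn("singular random-effects covariance estimate", stacklevel=2)
    return ModelFit(
        params=params,
        cov_re=cov_re,
        residual_var=float(result.scale),
        converged=bool(result.converged),
        singular_re=singular,
        n_obs=n,
        n_subjects=int(pd.unique(groups).size),
        primary_term=primary_term,
    )


def _check_min_subjects(table: pd.DataFrame, minimum: int) -> None:
    n = table["subject"].nunique()
    if n < minimum:
        raise ValueError(f"need at least {minimum} subjects, got {n}")


def fit_primary_model(table: pd.DataFrame, reml: bool = True) -> ModelFit:
    """Full-sample FC x PiB x time model; the three-way term is primary."""
    _check_min_subjects(table, 10)
    design = build_design(table, include_pib=True)
    return fit_lme(table, design, primary_term="fc:pib:time", reml=reml)


def fit_stratified_model(table: pd.DataFrame, group: str, reml: bool = True) -> ModelFit:
    """Within one amyloid group, the model without any PiB term.

    ``table`` must carry an ``amyloid_group`` column; the FC:time term is
    primary in the stratified fits.
    """
    if "amyloid_group" not in table.columns:
        raise ValueError("stratified fit requires an 'amyloid_group' column")
    sub = table[table["amyloid_group"] == group]
    if sub.empty:
        raise ValueError(f"no rows in amyloid group {group!r}")
    _check_min_subjects(sub, 5)
    design = build_design(sub, include_pib=False)
    return fit_lme(sub, design, primary_term="fc:time", reml=reml)


def fit_augmented_model(
    table: pd.DataFrame,
    extras: tuple[str, ...],
    group: str | None = "high",
    reml: bool = True,
) -> ModelFit:
    """Stratified model augmented with specificity covariates.

    ``extras`` selects blocks from :data:`EXTRA_TERMS` (FPCN connectivity
    with its time interaction, time-varying FPCN composite thickness, and/or
    inferior-temporal tau with its time interaction).  By default the model
    is fitted within the high-amyloid group, mirroring the post-hoc designs
    it supports; pass ``group=None`` for a full-sample augmented fit with
    PiB terms included.
    """
    if not extras:
        raise ValueError("augmented fit requires at least one extra term block")
    if group is not None:
        if "amyloid_group" not in table.columns:
            raise ValueError("grouped augmented fit requires an 'amyloid_group' column")
        table = table[table["amyloid_group"] == group]
        if table.empty:
            raise ValueError(f"no rows in amyloid group {group!r}")
        _check_min_subjects(table, 5)
        design = build_design(table, include_pib=False, extras=tuple(extras))
    else:
        _check_min_subjects(table, 10)
        design = build_design(table, include_pib=True, extras=tuple(extras))
    return fit_lme(table, design, primary_term="fc:time" if group else "fc:pib:time", reml=reml)


def effect_size_from_t(t: float, df: float) -> float:
    """Cohen's d recovered from a t statistic: d = 2t/sqrt(df), sign-preserving."""
    if df <= 0:
        raise ValueError("df must be positive")
    return 2.0 * t / np.sqrt(df)


def pooled_two_sample_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    variable: str = "",
) -> GroupComparison:
    """Pooled-variance two-sample t from summary statistics.

    sp^2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1+n2-2);
    t = |mean2 - mean1| / (sp sqrt(1/n1 + 1/n2)); df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    sp = np.sqrt(sp2)
    diff = abs(mean2 - mean1)
    if sp == 0.0:
        if diff == 0.0:
            t = 0.0
        else:
            raise ValueError("zero pooled variance with unequal means: infinite statistic")
    else:
        t = diff / (sp * np.sqrt(1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return GroupComparison(
        variable=variable,
        statistic=float(t),
        df=float(df),
        pvalue=float(p),
        detail={"mean1": mean1, "sd1": sd1, "n1": n1, "mean2": mean2, "sd2": sd2, "n2": n2},
    )


def chi_square_2x2(counts, variable: str = "") -> GroupComparison:
    """Pearson chi-square on a 2x2 count table, no continuity correction, df = 1."""
    obs = np.asarray(counts, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("counts must form a 2x2 table")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero margin in 2x2 table")
    expected = row @ col / total
    if np.any(expected <= 0):
        raise ValueError("expected counts must all be positive")
    stat = float(((obs - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(stat, 1))
    return GroupComparison(variable=variable, statistic=stat, df=1.0, pvalue=p)
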