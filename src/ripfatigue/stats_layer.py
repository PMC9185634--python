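"""Decile-level statistical models relating synchrony, EMG and kinematics.

Every metric is normalised before modelling: a Yeo-Johnson power transform
(lambda by maximum likelihood) followed by a z-score across the pooled
sample, so coefficients of different metrics share a scale.

Two mixed-effects specifications are fitted with a per-subject random
intercept (REML):

1. metric ~ trial + division           (trial and decile as categorical
   fixed effects, Baseline and division 1 as reference levels);
2. the same design plus EMG amplitude / median-frequency covariates, asking
   whether local muscle load predicts the respiratory metrics beyond the
   trial structure.

Residual assumptions are checked by a Wald test on the lag-1 residual
autocorrelation (independence), Shapiro-Wilk (normality) and White's
Lagrange-multiplier test (homoscedasticity).  Trial-level accelerometer
summaries are compared with one-way repeated-measures ANOVA (Mauchly
sphericity check, Greenhouse-Geisser correction when violated) and
Bonferroni-corrected paired t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sstats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.diagnostic import het_white
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .signal_model import DecileTable, ValidationError

__all__ = [
    "ALPHA",
    "MixedModelResult",
    "RMAnovaResult",
    "yeo_johnson_z",
    "fit_trial_division_model",
    "residual_diagnostics",
    "pearson_r",
    "rm_anova",
]

#: significance level (two-sided) used throughout
ALPHA = 0.05


@dataclass
class MixedModelResult:
    terms: list[tuple[str, float, float, float]]   # (name, beta, z, p)
    random_intercept_variance: float
    converged: bool
    residuals: np.ndarray = field(default=None, repr=False)
    design: pd.DataFrame = field(default=None, repr=False)
    groups: np.ndarray = field(default=None, repr=False)

    def term(self, name: str) -> tuple[float, float, float]:
        """(beta, z, p) for the fixed-effect term whose name contains ``name``."""
        hits = [t for t in self.terms if name in t[0]]
        if len(hits) != 1:
            raise KeyError(f"term {name!r} matched {len(hits)} coefficients")
        return hits[0][1:]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.terms, columns=["term", "beta", "z", "p"])
        df.loc[len(df)] = ["Subject variation", self.random_intercept_variance,
                           np.nan, np.nan]
        return df


@dataclass
class RMAnovaResult:
    F: float
    df: tuple[float, float]
    p: float
    partial_eta_sq: float
    sphericity_ok: bool
    correction: str                                  # "none" | "greenhouse_geisser"
    pairwise: list[tuple[str, float]]                # (pair, Bonferroni p)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"effect": "within", "F": self.F, "df1": self.df[0], "df2": self.df[1],
                 "p": self.p, "partial_eta_sq": self.partial_eta_sq,
                 "correction": self.correction}]
        return pd.DataFrame(rows)


def yeo_johnson_z(values) -> np.ndarray:
    """Yeo-Johnson transform (ML lambda) followed by a z-score: mean 0, SD 1."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)] if np.isnan(v).any() else v
    if v.size < 3:
        raise ValidationError("need at least 3 finite values")
    if np.ptp(v) == 0:
        raise ValidationError("cannot transform a constant sample")
    y, _ = sstats.yeojohnson(v)
    return (y - y.mean()) / y.std()


def _transformed_frame(table: DecileTable, metrics: list[str]) -> pd.DataFrame:
    """Wide frame with each requested metric Yeo-Johnson + z transformed (pooled)."""
    wide = table.pivot_metrics()
    for m in metrics:
        if m not in wide.columns:
            raise ValidationError(f"metric {m!r} not present in the table")
        if wide[m].isna().any():
            raise ValidationError(f"metric {m!r} has missing (subject, trial, division) cells")
        wide[m] = yeo_johnson_z(wide[m].to_numpy())
    return wide


def _quote(name: str) -> str:
    return f"Q('{name}')" if not name.isidentifier() else name


def fit_trial_division_model(table: DecileTable, dependent: str,
                             covariates: list[str] | None = None,
                             reml: bool = True) -> MixedModelResult:
    """Mixed-effects regression of a decile metric on trial, division and covariates.

    Fixed effects: trial (reference Baseline), division (reference 1) and any
    covariate metrics; random intercept per subject.  All variables are
    Yeo-Johnson + z transformed across the pooled sample before fitting.
    """
    covariates = list(covariates or [])
    wide = _transformed_frame(table, [dependent] + covariates)
    if wide["subject_id"].nunique() < 2:
        raise ValidationError("mixed model needs at least 2 subjects")
    rhs = ["C(trial, Treatment('Baseline'))", "C(division, Treatment(1))"]
    rhs += [_quote(c) for c in covariates]
    formula = f"{_quote(dependent)} ~ {' + '.join(rhs)}"
    model = smf.mixedlm(formula, data=wide, groups=wide["subject_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = model.fit(reml=reml, maxiter=200)
    terms = []
    for name in fit.fe_params.index:
        terms.append((_pretty_term(name), float(fit.fe_params[name]),
                      float(fit.tvalues[name]), float(fit.pvalues[name])))
    try:
        residuals = np.asarray(fit.resid)
    except ValueError:
        # singular random-effects covariance (e.g. variance estimated at 0):
        # fall back to marginal residuals about the fixed-effects fit
        residuals = np.asarray(model.endog) - model.exog @ np.asarray(fit.fe_params)
    return MixedModelResult(
        terms=terms,
        random_intercept_variance=float(np.asarray(fit.cov_re)[0, 0]),
        converged=bool(getattr(fit, "converged", True)),
        residuals=residuals,
        design=wide,
        groups=wide["subject_id"].to_numpy(),
    )


def _pretty_term(name: str) -> str:
    return (name
            .replace("C(trial, Treatment('Baseline'))[T.", "trial[")
            .replace("C(division, Treatment(1))[T.", "division[")
            .replace("Q('", "").replace("')", ""))


def residual_diagnostics(result: MixedModelResult) -> dict[str, dict[str, float]]:
    """Independence, normality and homoscedasticity checks on model residuals.

    Returns ``{test: {"statistic": ..., "p": ...}}`` with keys
    ``wald_independence`` (Wald test that the lag-1 residual autocorrelation,
    computed within subject, is zero), ``shapiro_wilk`` and ``white_lm``.
    Entries that cannot be computed are reported with NaNs.
    """
    resid = np.asarray(result.residuals, dtype=float)
    out: dict[str, dict[str, float]] = {}

    # Wald test on lag-1 autocorrelation, pairs taken within subject only
    pairs_x, pairs_y = [], []
    for g in pd.unique(result.groups):
        e = resid[result.groups == g]
        if e.size >= 2:
            pairs_x.append(e[:-1])
            pairs_y.append(e[1:])
    if pairs_x and sum(p.size for p in pairs_x) >= 10:
        x = np.concatenate(pairs_x)
        y = np.concatenate(pairs_y)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        z = float(ols.params[1] / ols.bse[1])
        out["wald_independence"] = {"statistic": z,
                                    "p": float(2 * sstats.norm.sf(abs(z)))}
    else:
        out["wald_independence"] = {"statistic": float("nan"), "p": float("nan")}

    if 3 <= resid.size <= 5000:
        w, p = sstats.shapiro(resid)
        out["shapiro_wilk"] = {"statistic": float(w), "p": float(p)}
    else:
        out["shapiro_wilk"] = {"statistic": float("nan"), "p": float("nan")}

    try:
        exog = pd.get_dummies(result.design[["trial", "division"]].astype(str),
                              drop_first=True, dtype=float)
        exog = sm.add_constant(exog.to_numpy())
        lm, lm_p, _, _ = het_white(resid, exog)
        out["white_lm"] = {"statistic": float(lm), "p": float(lm_p)}
    except Exception:
        out["white_lm"] = {"statistic": float("nan"), "p": float("nan")}
    return out


def pearson_r(a, b) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValidationError("need two equal-length sequences of at least 3 values")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("correlation undefined for a constant sequence")
    res = sstats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def rm_anova(per_subject_trial: pd.DataFrame, metric: str,
             subject: str = "subject_id", within: str = "trial") -> RMAnovaResult:
    """One-way repeated-measures ANOVA across trials with pairwise follow-up.

    Expects one row per (subject, trial).  Sphericity is assessed by
    Mauchly's test; when rejected, Greenhouse-Geisser corrected degrees of
    freedom and p-value are reported.  Pairwise paired t-tests use Bonferroni
    correction (p multiplied by the number of pairs, capped at 1).
    """
    df = per_subject_trial[[subject, within, metric]].dropna()
    counts = df.groupby(within)[subject].nunique()
    if counts.nunique() != 1 or df.duplicated([subject, within]).any():
        raise ValidationError("need a complete subject x trial table")
    levels = list(df[within].unique())
    if len(levels) < 2:
        raise ValidationError("need at least two within-subject conditions")

    wide_vals = df.pivot(index=subject, columns=within, values=metric)
    k = len(levels)
    n_sub = wide_vals.shape[0]
    mat = wide_vals.to_numpy(dtype=float)
    df1_nom, df2_nom = float(k - 1), float((k - 1) * (n_sub - 1))
    if np.allclose(mat, mat[:, [0]]):
        # no within-subject variation at all: F = 0 by definition
        pairs = [(f"{i} vs {j}", 1.0) for a, i in enumerate(levels) for j in levels[a + 1:]]
        return RMAnovaResult(F=0.0, df=(df1_nom, df2_nom), p=1.0, partial_eta_sq=0.0,
                             sphericity_ok=True, correction="none", pairwise=pairs)
    resid = mat - mat.mean(axis=1, keepdims=True) - mat.mean(axis=0) + mat.mean()
    if np.sum(resid ** 2) < 1e-12 * np.sum((mat - mat.mean()) ** 2):
        # deterministic condition effects: residual MS is 0 and F diverges
        combos = [(i, j) for a, i in enumerate(levels) for j in levels[a + 1:]]
        pairs = [(f"{i} vs {j}",
                  1.0 if np.allclose(wide_vals[i], wide_vals[j]) else 0.0)
                 for i, j in combos]
        return RMAnovaResult(F=float("inf"), df=(df1_nom, df2_nom), p=0.0,
                             partial_eta_sq=1.0, sphericity_ok=True,
                             correction="none", pairwise=pairs)

    # Mauchly's test needs more subjects than conditions
    assess_sphericity = k > 2 and n_sub > k
    aov = pg.rm_anova(data=df, dv=metric, within=within, subject=subject,
                      correction=assess_sphericity, detailed=True, effsize="np2")
    row = aov.iloc[0]
    if assess_sphericity and "sphericity" in aov.columns and not pd.isna(row["sphericity"]):
        sphericity_ok = bool(row["sphericity"])
    else:
        sphericity_ok = True  # two levels (or too few subjects): not assessable

    df1, df2 = float(row["DF"]), float(aov.iloc[1]["DF"])
    p = float(row["p_unc"])
    correction = "none"
    if not sphericity_ok:
        eps = float(row["eps"])
        df1, df2 = df1 * eps, df2 * eps
        p = float(row["p_GG_corr"])
        correction = "greenhouse_geisser"

    wide = df.pivot(index=subject, columns=within, values=metric)
    pairs: list[tuple[str, float]] = []
    combos = [(i, j) for k, i in enumerate(levels) for j in levels[k + 1:]]
    for i, j in combos:
        t, praw = sstats.ttest_rel(wide[i], wide[j])
        pairs.append((f"{i} vs {j}", float(min(1.0, len(combos) * praw))))

    return RMAnovaResult(F=float(row["F"]), df=(df1, df2), p=p,
                         partial_eta_sq=float(row["np2"]),
                         sphericity_ok=sphericity_ok, correction=correction,
                         pairwise=pairs)
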