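"""Statistical inference stages.

The centrepiece is a multilevel (random-intercept) regression of the
post/pre change in SAI on session-specific recalibration: four predictors —
{veridical, conflict} session x {proprioceptive, visual} recalibration — plus
an intercept, with a participant-level random intercept estimated by REML.
Collinearity among the predictors is screened with variance inflation
factors, and predictor-residual helpers support the corresponding partial
scatter plots.  The remaining operations wrap the standard univariate tests
used around that model: a 2x2 within-subject ANOVA (session x time), one-way
group comparisons with Tukey HSD or a Kruskal-Wallis fallback, Pearson
correlations, and one-sample t tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

ALPHA = 0.05

SESSIONS = ("veridical", "conflict")
MODALITIES = ("recal_p", "recal_v")
#: Predictor order of the reduced SAI model (intercept first when reported).
SAI_MODEL_TERMS = tuple(
    f"{session}:{modality}" for session in SESSIONS for modality in MODALITIES
)


class InferenceError(ValueError):
    """Raised for malformed inputs to a statistical stage."""


class CollinearityError(InferenceError):
    """Raised when model predictors are exactly linearly dependent."""


@dataclass(frozen=True)
class TermResult:
    name: str
    beta: float
    ci_low: float
    ci_high: float
    t: float
    df: float
    p: float


@dataclass
class ModelFit:
    terms: list[TermResult]
    vif: dict[str, float]
    n_participants: int
    n_observations: int
    converged: bool
    random_intercept_sd: float

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p: float
    method: str
    effect_size: float | None = None
    pairwise: pd.DataFrame | None = field(default=None, compare=False)


# ---------------------------------------------------------------------------
# Multilevel SAI ~ session x recalibration model
# ---------------------------------------------------------------------------

def _design_matrix(table: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(index=table.index)
    for session in SESSIONS:
        mask = (table["session"] == session).astype(float)
        for modality in MODALITIES:
            X[f"{session}:{modality}"] = mask * table[modality]
    return X


def compute_vifs(X: pd.DataFrame) -> dict[str, float]:
    """VIF_j = 1 / (1 - R^2_j) from regressing predictor j on the others.

    Exact linear dependence among predictors raises ``CollinearityError``
    rather than returning an astronomically large value.
    """
    vifs: dict[str, float] = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=[col]))
        r2 = sm.OLS(X[col], others).fit().rsquared
        if r2 > 1 - 1e-10:
            raise CollinearityError(f"predictor {col!r} is collinear with the others")
        vifs[col] = 1.0 / (1.0 - r2)
    return vifs


def fit_sai_recalibration_model(table: pd.DataFrame) -> ModelFit:
    """Fit delta-SAI on session-specific recalibration with a random intercept.

    ``table`` has one row per participant x session with columns
    ``participant``, ``session`` ('conflict' or 'veridical'), ``delta_sai``,
    ``recal_p``, ``recal_v``.  Participants missing a session are dropped
    (with a warning).  Inference uses the residual-degrees-of-freedom
    convention df = n_observations - 5 (five fixed effects) with Wald 95%
    CIs.  If the REML fit fails or the random-intercept variance collapses
    onto the boundary, an ordinary least-squares fit is reported with
    ``converged=False``.
    """
    required = {"participant", "session", "delta_sai", "recal_p", "recal_v"}
    if missing := required - set(table.columns):
        raise InferenceError(f"missing columns: {sorted(missing)}")
    counts = table.groupby("participant")["session"].nunique()
    complete = counts[counts == len(SESSIONS)].index
    if len(complete) < len(counts):
        warnings.warn(
            f"dropping {len(counts) - len(complete)} participant(s) missing a session",
            stacklevel=2,
        )
    data = table[table["participant"].isin(complete)].reset_index(drop=True)
    if data.empty:
        raise InferenceError("no participant has both sessions")

    X = _design_matrix(data)
    vifs = compute_vifs(X)
    y = data["delta_sai"].to_numpy(dtype=float)
    exog = sm.add_constant(X)
    n_obs = len(data)
    df_resid = n_obs - exog.shape[1]

    converged = True
    re_sd = 0.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mlm = sm.MixedLM(y, exog, groups=data["participant"]).fit(reml=True)
        re_sd = float(np.sqrt(max(float(mlm.cov_re.iloc[0, 0]), 0.0)))
        params = mlm.params[: exog.shape[1]]
        bse = mlm.bse[: exog.shape[1]]
        if not mlm.converged or not np.all(np.isfinite(bse)):
            raise RuntimeError("mixed model did not converge")
    except Exception:
        converged = False
        ols = sm.OLS(y, exog).fit()
        params, bse = ols.params, ols.bse

    t_crit = stats.t.ppf(0.975, df_resid)
    terms = []
    names = ["intercept"] + list(X.columns)
    for name, beta, se in zip(names, np.asarray(params), np.asarray(bse)):
        tval = beta / se if se > 0 else 0.0
        pval = 2 * stats.t.sf(abs(tval), df_resid)
        terms.append(
            TermResult(
                name=name,
                beta=float(beta),
                ci_low=float(beta - t_crit * se),
                ci_high=float(beta + t_crit * se),
                t=float(tval),
                df=float(df_resid),
                p=float(pval),
            )
        )
    return ModelFit(
        terms=terms,
        vif=vifs,
        n_participants=int(data["participant"].nunique()),
        n_observations=n_obs,
        converged=converged,
        random_intercept_sd=re_sd,
    )


def predictor_residuals(
    table: pd.DataFrame, target_predictor: str, other_predictor: str
) -> pd.DataFrame:
    """Residuals of the target predictor after regressing out the other.

    Returns the residuals paired with ``delta_sai`` (when present) for
    predictor-residual scatter plots that isolate the unique contribution of
    the predictor of interest.
    """
    if len(table) < 3:
        raise InferenceError("need at least 3 rows")
    target = table[target_predictor].to_numpy(dtype=float)
    other = table[other_predictor].to_numpy(dtype=float)
    if np.var(other) == 0:
        resid = target - target.mean()
    else:
        fit = sm.OLS(target, sm.add_constant(other)).fit()
        resid = fit.resid
    out = pd.DataFrame({f"{target_predictor}_resid": resid})
    if "delta_sai" in table.columns:
        out["delta_sai"] = table["delta_sai"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# ANOVAs, correlations, one-sample tests
# ---------------------------------------------------------------------------

def rm_anova_2x2(
    data: pd.DataFrame,
    subject: str,
    factor_a: str,
    factor_b: str,
    value: str,
) -> dict[str, TestResult]:
    """Two-by-two fully within-subject ANOVA (e.g. session x time).

    Uses the exact equivalence, for a 2x2 within design, of each F(1, n-1)
    to the squared paired t of the corresponding difference-score contrast.
    Returns results keyed by the factor names and ``"interaction"``.
    """
    levels_a = sorted(data[factor_a].unique())
    levels_b = sorted(data[factor_b].unique())
    if len(levels_a) != 2 or len(levels_b) != 2:
        raise InferenceError("both factors must have exactly 2 levels")
    cells = data.pivot_table(
        index=subject, columns=[factor_a, factor_b], values=value
    )
    if cells.isna().any().any() or cells.shape[1] != 4:
        raise InferenceError("incomplete 2x2 within-subject data")
    a1b1 = cells[(levels_a[0], levels_b[0])]
    a1b2 = cells[(levels_a[0], levels_b[1])]
    a2b1 = cells[(levels_a[1], levels_b[0])]
    a2b2 = cells[(levels_a[1], levels_b[1])]
    contrasts = {
        factor_a: (a2b1 + a2b2 - a1b1 - a1b2) / 2,
        factor_b: (a1b2 + a2b2 - a1b1 - a2b1) / 2,
        "interaction": (a2b2 - a2b1) - (a1b2 - a1b1),
    }
    n = cells.shape[0]
    out = {}
    for name, c in contrasts.items():
        c = c.to_numpy(dtype=float)
        sd = c.std(ddof=1)
        if sd == 0:
            # degenerate contrast: identically zero (no effect) or exactly
            # constant and non-zero (infinite evidence)
            f = 0.0 if c.mean() == 0 else np.inf
            p = 1.0 if f == 0 else 0.0
        else:
            t = c.mean() / (sd / np.sqrt(n))
            f = t**2
            p = float(stats.f.sf(f, 1, n - 1))
        out[name] = TestResult(
            statistic=float(f), df=(1.0, float(n - 1)), p=p, method="rm_anova_2x2"
        )
    return out


def group_comparison(
    values: np.ndarray,
    groups: np.ndarray,
    method: str = "anova_tukey",
) -> TestResult:
    """One-way comparison of three groups.

    ``anova_tukey``: omnibus F with eta-squared, followed by Tukey-HSD
    pairwise comparisons when the omnibus is significant at alpha = 0.05.
    ``kruskal_wallis``: rank-based H with tie correction (used when
    normality or homogeneity assumptions fail).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 3:
        raise InferenceError("need at least 3 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) < 2 for s in samples):
        raise InferenceError("need at least 2 observations per group")
    if method == "anova_tukey":
        f, p = stats.f_oneway(*samples)
        grand = values.mean()
        ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
        ss_total = float(((values - grand) ** 2).sum())
        eta_sq = ss_between / ss_total if ss_total > 0 else 0.0
        pairwise = None
        if p < ALPHA:
            tk = pairwise_tukeyhsd(values, groups, alpha=ALPHA)
            pairwise = pd.DataFrame(
                tk.summary().data[1:], columns=tk.summary().data[0]
            )
        df = (float(len(labels) - 1), float(len(values) - len(labels)))
        return TestResult(
            statistic=float(f), df=df, p=float(p), method="anova",
            effect_size=float(eta_sq), pairwise=pairwise,
        )
    if method == "kruskal_wallis":
        h, p = stats.kruskal(*samples)
        return TestResult(
            statistic=float(h), df=float(len(labels) - 1), p=float(p),
            method="kruskal_wallis",
        )
    raise InferenceError(f"unknown method {method!r}")


def pearson_r(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Pearson correlation with two-tailed p on df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InferenceError("need n >= 3 paired finite values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InferenceError("inputs must be finite")
    if np.var(x) == 0 or np.var(y) == 0:
        raise InferenceError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return TestResult(
        statistic=float(r), df=float(len(x) - 2), p=float(p),
        method="pearson", effect_size=float(r),
    )


def one_sample_t(values: np.ndarray, mu0: float = 0.0) -> TestResult:
    """Two-tailed one-sample t test with Cohen's d = (mean - mu0) / sd."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise InferenceError("need n >= 2")
    sd = values.std(ddof=1)
    if sd == 0:
        raise InferenceError("zero standard deviation")
    res = stats.ttest_1samp(values, mu0)
    d = (values.mean() - mu0) / sd
    return TestResult(
        statistic=float(res.statistic), df=float(len(values) - 1),
        p=float(res.pvalue), method="one_sample_t", effect_size=float(d),
    )
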