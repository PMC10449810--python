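"""Cohort association analyses: transforms, correlations, OLS/ridge regression,
likelihood-ratio tests, and the biomarker heterogeneity scan.

All regressions adjust for age, sex, BMI, height and current smoking; imaging
metrics enter as centred/scaled natural-log values so coefficient magnitudes
are directly comparable.  Ridge regression is used where metric collinearity
is severe, with the ridge parameter chosen from the Kibria/Muniz estimator
family (default: Kibria geometric mean) and sandwich-form standard errors

    Var(β̂) = σ̂² (XᵀX + kI)⁻¹ XᵀX (XᵀX + kI)⁻¹.

The biomarker scan compares, per marker, a base model (demographics + %LAA)
against models augmented with emphysema heterogeneity phenotypes: EHP2 adds
{NJC, D}; EHP4 adds {NJC, D, ACS, NC}.  Continuous markers use Gaussian
likelihood-ratio tests, binarized (present/absent) markers logistic ones, and
Benjamini–Hochberg FDR control is applied within each phenotype column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

DEFAULT_COVARIATES = ("age", "sex_male", "bmi", "height", "smoker")
EHP2_METRICS = ("njc", "D")
EHP4_METRICS = ("njc", "D", "acs", "nc")

RIDGE_K_METHODS = ("hoerl_kennard", "hoerl_kennard_baldwin",
                   "kibria_am", "kibria_gm", "kibria_med")


# ---------------------------------------------------------------------------
# Result containers


@dataclass(frozen=True)
class RegressionResult:
    term: str
    coefficient: float
    std_error: float
    p_value: float
    r_squared: float
    adj_r_squared: float
    n: int
    model: str


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float
    full: str
    reduced: str


@dataclass(frozen=True)
class RidgeFit:
    k: float
    k_method: str
    terms: list
    r_squared: float
    adj_r_squared: float
    n: int
    model: str

    def term(self, name: str) -> RegressionResult:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)


@dataclass(frozen=True)
class LogStandardized:
    values: pd.Series
    offset: float
    log_mean: float
    log_sd: float


# ---------------------------------------------------------------------------
# Transforms


def log_standardize(values) -> LogStandardized:
    """Centre/scale natural-log values: z = (ln(x + c) − mean) / sd.

    The offset c is zero for strictly positive columns; if any value is
    exactly zero, half the smallest positive value is added (and recorded)
    so the log is defined.
    """
    x = pd.Series(values).astype(float)
    if (x < 0).any():
        raise ValueError("log_standardize requires nonnegative values")
    offset = 0.0
    if (x == 0).any():
        positive = x[x > 0]
        if positive.empty:
            raise ValueError("column is identically zero")
        offset = float(positive.min()) / 2.0
    logged = np.log(x + offset)
    sd = float(logged.std(ddof=1))
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("column has zero variance after log transform")
    mean = float(logged.mean())
    return LogStandardized(values=(logged - mean) / sd, offset=offset,
                           log_mean=mean, log_sd=sd)


def standardize_metrics(cohort: pd.DataFrame, metrics) -> pd.DataFrame:
    """Z-scaled log transform of each metric column, suffixed ``_z``."""
    out = cohort.copy()
    for m in metrics:
        out[f"{m}_z"] = log_standardize(cohort[m]).values
    return out


def correlation_matrix(metrics: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson and Spearman correlation matrices (pairwise-complete rows)."""
    for col in metrics.columns:
        x = metrics[col].dropna()
        if x.nunique() < 2:
            raise ValueError(f"column {col!r} is constant")
        if len(x) < 3:
            raise ValueError(f"column {col!r} has fewer than 3 complete rows")
    return metrics.corr(method="pearson"), metrics.corr(method="spearman")


# ---------------------------------------------------------------------------
# OLS


def _design(cohort: pd.DataFrame, columns) -> pd.DataFrame:
    """Design matrix with intercept; categoricals dummy-coded (first level ref)."""
    blocks = [pd.Series(1.0, index=cohort.index, name="const")]
    for col in columns:
        s = cohort[col]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            blocks.append(dummies)
        else:
            blocks.append(s.astype(float))
    return pd.concat(blocks, axis=1)


def fit_univariate(
    cohort: pd.DataFrame,
    outcome: str,
    metric_z: str,
    covariates=DEFAULT_COVARIATES,
) -> RegressionResult:
    """OLS of one outcome on one z-scaled metric plus demographic covariates."""
    cols = [outcome, metric_z, *covariates]
    data = cohort[cols].dropna()
    X = _design(data, [metric_z, *covariates])
    if len(data) < X.shape[1] + 2:
        raise ValueError("too few complete rows for the design")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates)")
    fit = sm.OLS(data[outcome].astype(float), X).fit()
    return RegressionResult(
        term=metric_z,
        coefficient=float(fit.params[metric_z]),
        std_error=float(fit.bse[metric_z]),
        p_value=float(fit.pvalues[metric_z]),
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        n=int(fit.nobs),
        model=f"{outcome} ~ {metric_z} + covariates",
    )


# ---------------------------------------------------------------------------
# Ridge


def estimate_ridge_k(X: np.ndarray, y: np.ndarray, method: str = "kibria_gm") -> float:
    """Ridge parameter from the Kibria/Muniz estimator family.

    Computed in the canonical (principal-component) form of the standardized
    design: with α̂ the rotated OLS coefficients and σ̂² the OLS residual
    variance, the implemented estimators are Hoerl–Kennard σ̂²/max α̂ᵢ²,
    Hoerl–Kennard–Baldwin p·σ̂²/Σα̂ᵢ², and the arithmetic-mean, geometric-mean
    and median forms of m̂ᵢ = σ̂²/α̂ᵢ².
    """
    if method not in RIDGE_K_METHODS:
        raise ValueError(f"unknown ridge-k method {method!r}; choose from {RIDGE_K_METHODS}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise ValueError("rank-deficient design")
    resid = y - X @ beta
    dof = n - p - 1  # intercept removed upstream by centring
    sigma2 = float(resid @ resid) / max(dof, 1)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    alpha = vt @ beta
    alpha2 = np.maximum(alpha**2, 1e-12)
    if method == "hoerl_kennard":
        return sigma2 / float(alpha2.max())
    if method == "hoerl_kennard_baldwin":
        return p * sigma2 / float(alpha2.sum())
    m = sigma2 / alpha2
    if method == "kibria_am":
        return float(m.mean())
    if method == "kibria_gm":
        return float(np.exp(np.log(m).mean()))
    return float(np.median(m))


def fit_ridge(
    cohort: pd.DataFrame,
    outcome: str,
    metric_zs,
    covariates=DEFAULT_COVARIATES,
    k: float | None = None,
    k_method: str = "kibria_gm",
) -> RidgeFit:
    """Ridge regression of an outcome on several z-scaled metrics + covariates.

    Predictors are standardized before the penalty and the intercept is never
    penalized (it is removed by centring).  With k = 0 this reproduces OLS.
    Coefficients are reported on the standardized-predictor scale; the
    adjusted R² uses the raw predictor count.
    """
    predictors = [*metric_zs, *covariates]
    data = cohort[[outcome, *predictors]].dropna()
    raw = data[predictors].astype(float).to_numpy()
    sds = raw.std(axis=0, ddof=1)
    if (sds == 0).any():
        raise ValueError("constant predictor column")
    Z = (raw - raw.mean(axis=0)) / sds
    yv = data[outcome].astype(float).to_numpy()
    yc = yv - yv.mean()
    n, p = Z.shape
    if np.linalg.matrix_rank(Z) < p and (k == 0 or (k is None and n <= p)):
        raise ValueError("design singular and unpenalized")
    if k is None:
        k = estimate_ridge_k(Z, yc, method=k_method)
    if k < 0:
        raise ValueError("ridge parameter must be nonnegative")

    ZtZ = Z.T @ Z
    A = ZtZ + k * np.eye(p)
    A_inv = np.linalg.inv(A)
    beta = A_inv @ Z.T @ yc
    fitted = Z @ beta
    rss = float(((yc - fitted) ** 2).sum())
    tss = float((yc**2).sum())
    dof = n - p - 1
    sigma2 = rss / max(dof, 1)
    cov = sigma2 * (A_inv @ ZtZ @ A_inv)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=max(dof, 1))
    r2 = 1.0 - rss / tss
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / max(dof, 1)

    terms = [
        RegressionResult(term=name, coefficient=float(b), std_error=float(s),
                         p_value=float(pv), r_squared=r2, adj_r_squared=adj_r2,
                         n=n, model=f"ridge(k={k:.4g})")
        for name, b, s, pv in zip(predictors, beta, se, pvals)
    ]
    return RidgeFit(k=float(k), k_method=k_method, terms=terms, r_squared=r2,
                    adj_r_squared=adj_r2, n=n,
                    model=f"{outcome} ~ ridge({', '.join(predictors)})")


def adjusted_r2_gain(
    cohort: pd.DataFrame,
    outcome: str,
    full_metrics,
    reduced_metrics,
    covariates=DEFAULT_COVARIATES,
    k_method: str = "kibria_gm",
) -> tuple[float, float]:
    """Adjusted R² of the full and reduced ridge models (each with its own k)."""
    full = fit_ridge(cohort, outcome, full_metrics, covariates, k_method=k_method)
    if list(full_metrics) == list(reduced_metrics):
        return full.adj_r_squared, full.adj_r_squared
    reduced = fit_ridge(cohort, outcome, reduced_metrics, covariates, k_method=k_method)
    return full.adj_r_squared, reduced.adj_r_squared


# ---------------------------------------------------------------------------
# Likelihood-ratio tests


def likelihood_ratio_test(
    cohort: pd.DataFrame,
    outcome: str,
    full_terms,
    reduced_terms,
    family: str = "gaussian",
) -> LRTResult:
    """LRT between nested regression models on identical rows.

    Gaussian models use the maximum-likelihood statistic n·ln(RSS_r / RSS_f);
    logistic models use the deviance difference.  The reference distribution
    is χ² with df equal to the parameter-count difference (a categorical term
    contributes one df per non-reference level).
    """
    if not set(reduced_terms) <= set(full_terms):
        raise ValueError("reduced model terms must be a subset of the full model's")
    cols = [outcome, *dict.fromkeys([*full_terms, *reduced_terms])]
    data = cohort[cols].dropna()
    X_full = _design(data, list(full_terms))
    X_red = _design(data, list(reduced_terms))
    y = data[outcome].astype(float)
    df = X_full.shape[1] - X_red.shape[1]
    if df < 0:
        raise ValueError("full model has fewer parameters than reduced model")

    if family == "gaussian":
        stat = _gaussian_lrt_stat(y.to_numpy(), X_full.to_numpy(), X_red.to_numpy())
    elif family == "logistic":
        fit_f = sm.Logit(y, X_full).fit(disp=0)
        fit_r = sm.Logit(y, X_red).fit(disp=0)
        stat = 2.0 * (fit_f.llf - fit_r.llf)
    else:
        raise ValueError(f"unknown family {family!r}")
    stat = max(float(stat), 0.0)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return LRTResult(statistic=stat, df=df, p_value=p,
                     full=" + ".join(full_terms), reduced=" + ".join(reduced_terms))


def _gaussian_lrt_stat(y, X_full, X_red) -> float:
    n = len(y)
    rss_f = _rss(y, X_full)
    rss_r = _rss(y, X_red)
    if rss_f <= 0:
        return np.inf
    return n * np.log(rss_r / rss_f)


def _rss(y, X) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


# ---------------------------------------------------------------------------
# Biomarker preprocessing and EHP scan


@dataclass(frozen=True)
class BiomarkerPanel:
    values: pd.DataFrame        # transformed columns (continuous + binary)
    classes: pd.Series          # per marker: excluded / binary / continuous
    below_lloq_fraction: pd.Series


def preprocess_biomarkers(raw: pd.DataFrame, lloq: pd.Series) -> BiomarkerPanel:
    """Classify and transform a raw abundance table given per-marker LLOQs.

    Markers with a below-LLOQ fraction above 0.95 are excluded; fractions in
    (0.10, 0.95] become binary present/absent indicators; the rest receive an
    empirical normal-quantile transform Φ⁻¹((rank − 0.5)/n) with average ranks
    for ties and below-LLOQ values ranked lowest.
    """
    missing = [c for c in raw.columns if c not in lloq.index]
    if missing:
        raise ValueError(f"markers without LLOQ: {missing}")
    classes, fractions, cols = {}, {}, {}
    n = len(raw)
    for marker in raw.columns:
        x = raw[marker].astype(float)
        below = x < lloq[marker]
        frac = float(below.mean())
        fractions[marker] = frac
        if frac > 0.95:
            classes[marker] = "excluded"
            continue
        if frac > 0.10:
            classes[marker] = "binary"
            cols[marker] = (~below).astype(float)
            continue
        classes[marker] = "continuous"
        work = x.copy()
        if below.any():
            work[below] = -np.inf   # lowest ranks; ties averaged among them
        ranks = work.rank(method="average")
        cols[marker] = pd.Series(stats.norm.ppf((ranks - 0.5) / n), index=raw.index)
    return BiomarkerPanel(values=pd.DataFrame(cols, index=raw.index),
                          classes=pd.Series(classes, name="class"),
                          below_lloq_fraction=pd.Series(fractions, name="below_lloq"))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 0:
        return p
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


@dataclass(frozen=True)
class BiomarkerScanResult:
    table: pd.DataFrame          # per marker: class, p/q for EHP2 and EHP4, flags
    fdr: float

    @property
    def n_ehp2_discoveries(self) -> int:
        return int(self.table["ehp2_significant"].sum())

    @property
    def n_ehp4_discoveries(self) -> int:
        return int(self.table["ehp4_significant"].sum())


def run_ehp_biomarker_scan(
    cohort: pd.DataFrame,
    markers: pd.DataFrame,
    lloq: pd.Series,
    covariates=DEFAULT_COVARIATES,
    fdr: float = 0.10,
) -> BiomarkerScanResult:
    """Per-marker LRTs of EHP2 and EHP4 models against the %LAA base model.

    The base model regresses the (transformed) marker on demographics + %LAA;
    EHP2 adds {NJC, D}, EHP4 adds {NJC, D, ACS, NC} (all z-scaled logs).
    BH adjustment is applied separately within the EHP2 and EHP4 columns and
    markers are flagged at the given FDR.
    """
    panel = preprocess_biomarkers(markers, lloq)
    work = standardize_metrics(cohort, ("pct_laa", *EHP4_METRICS))
    base_terms = [*covariates, "pct_laa_z"]
    ehp2_terms = base_terms + [f"{m}_z" for m in EHP2_METRICS]
    ehp4_terms = base_terms + [f"{m}_z" for m in EHP4_METRICS]

    rows = []
    for marker in panel.values.columns:
        cls = panel.classes[marker]
        family = "logistic" if cls == "binary" else "gaussian"
        tmp = work.copy()
        tmp["_marker"] = panel.values[marker]
        lrt2 = likelihood_ratio_test(tmp, "_marker", ehp2_terms, base_terms, family)
        lrt4 = likelihood_ratio_test(tmp, "_marker", ehp4_terms, base_terms, family)
        rows.append({"marker": marker, "class": cls,
                     "ehp2_p": lrt2.p_value, "ehp4_p": lrt4.p_value})
    table = pd.DataFrame(rows).set_index("marker")
    if len(table):
        table["ehp2_q"] = bh_adjust(table["ehp2_p"].clip(lower=np.nextafter(0, 1)))
        table["ehp4_q"] = bh_adjust(table["ehp4_p"].clip(lower=np.nextafter(0, 1)))
        table["ehp2_significant"] = table["ehp2_q"] < fdr
        table["ehp4_significant"] = table["ehp4_q"] < fdr
    excluded = panel.classes[panel.classes == "excluded"]
    for marker in excluded.index:
        table.loc[marker] = {"class": "excluded", "ehp2_p": np.nan, "ehp4_p": np.nan,
                             "ehp2_q": np.nan, "ehp4_q": np.nan,
                             "ehp2_significant": False, "ehp4_significant": False}
    return BiomarkerScanResult(table=table, fdr=fdr)
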