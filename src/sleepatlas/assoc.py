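"""Survey-weighted metabolome-wide association scan.

Each metabolite (rank-normalised outcome) is regressed on each sleep
phenotype plus covariates under the complex sampling design.  Point estimates
come from weighted least squares; standard errors from Taylor-linearised
between-PSU variance within strata, the standard design-based ("sandwich")
estimator for stratified multistage samples.  The design degrees of freedom
are ``d = #PSUs - #strata``.

Linear and binary exposures contribute one coefficient; circular clock-time
exposures enter as sine and cosine of the angle ``theta = 2*pi*minutes/1440``
(midnight is 0) and are tested jointly with a multivariate Wald test against
``F(q, d - q + 1)``.  Across the m multiply-imputed datasets, single
coefficients are pooled with Rubin's rules (Barnard-Rubin degrees of
freedom), while circular tests — whose sine/cosine covariance has no
multiple-imputation pooling rule — are combined on the p-value scale with the
aggregated Cauchy association test (ACAT).  Benjamini-Hochberg FDR is applied
across metabolites within each (phenotype, model, stratum) family, and an
association is flagged significant when its Model-1 FDR-adjusted p-value is
below 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .covmodel import CovariateSpec, build_covariate_design
from .preprocess import ImputedStack
from .synthdata import PhenotypeTable

MODEL1_COVARIATES = ["batch", "age", "sex", "centre", "background", "bmi"]
MODEL2_EXTRA = ["alcohol", "smoking", "physact", "diet"]
CATEGORICAL_COVARIATES = {"centre", "background", "alcohol", "smoking"}
P_FLOOR = 1e-15


@dataclass
class DesignInfo:
    """Stratum / PSU / weight triple describing the sampling design."""

    strata: np.ndarray
    psus: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.strata = np.asarray(self.strata)
        self.psus = np.asarray(self.psus)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (len(self.strata) == len(self.psus) == len(self.weights)):
            raise ValueError("strata, psus and weights must have equal length")
        if (self.weights <= 0).any():
            raise ValueError("sampling weights must be strictly positive")
        psu_strata = pd.DataFrame({"s": self.strata, "p": self.psus})
        per_psu = psu_strata.groupby("p")["s"].nunique()
        if (per_psu > 1).any():
            raise ValueError("each PSU must belong to exactly one stratum")
        counts = psu_strata.drop_duplicates().groupby("s").size()
        lonely = counts.index[counts < 2]
        if len(lonely):
            raise ValueError(
                f"stratum(s) {list(lonely)} have a single PSU; "
                "between-PSU variance needs >= 2 PSUs per stratum")
        if self.design_df < 1:
            raise ValueError("design degrees of freedom must be >= 1")

    @property
    def design_df(self) -> int:
        """d = #PSUs - #strata."""
        n_psu = pd.DataFrame({"s": self.strata, "p": self.psus}).drop_duplicates().shape[0]
        return int(n_psu - len(np.unique(self.strata)))

    def psu_groups(self):
        """Cached [(n_h/(n_h-1), [row-index arrays per PSU]), ...] per stratum."""
        if not hasattr(self, "_psu_groups"):
            groups = []
            frame = pd.DataFrame({"s": self.strata, "p": self.psus})
            for s, sub in frame.groupby("s"):
                rows = [sub.index[sub["p"] == pid].to_numpy()
                        for pid in sub["p"].unique()]
                n_h = len(rows)
                groups.append((n_h / (n_h - 1), rows))
            self._psu_groups = groups
        return self._psu_groups

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame) -> "DesignInfo":
        return cls(strata=cohort["stratum"].to_numpy(),
                   psus=cohort["psu"].to_numpy(),
                   weights=cohort["weight"].to_numpy())

    def subset(self, mask: np.ndarray) -> "DesignInfo":
        return DesignInfo(self.strata[mask], self.psus[mask], self.weights[mask])


@dataclass
class FitResult:
    """Weighted fit with linearised covariance and exposure-term bookkeeping."""

    beta: np.ndarray
    cov: np.ndarray
    df: int
    n: int
    exposure_idx: list[int]
    columns: list[str]

    def exposure_estimates(self) -> np.ndarray:
        return self.beta[self.exposure_idx]

    def exposure_cov(self) -> np.ndarray:
        return self.cov[np.ix_(self.exposure_idx, self.exposure_idx)]


@dataclass
class PooledResult:
    """Rubin-pooled single coefficient, or an ACAT-pooled p for circular terms."""

    estimate: float | None
    se: float | None
    df: float | None
    p: float
    within_var: float | None = None
    between_var: float | None = None


def encode_circular(time_minutes) -> tuple:
    """Map minutes past midnight to (sin, cos) of theta = 2*pi*t/1440.

    Midnight encodes to (0, 1).  Values outside [0, 1440) are wrapped with a
    warning.  Accepts scalars or arrays.
    """
    t = np.asarray(time_minutes, dtype=float)
    if ((t < 0) | (t >= 1440)).any():
        warnings.warn("clock-time values outside [0, 1440) were wrapped",
                      stacklevel=2)
        t = np.mod(t, 1440.0)
    theta = 2 * np.pi * t / 1440.0
    return np.sin(theta), np.cos(theta)


def fit_weighted_lm(
    outcome: np.ndarray,
    design_matrix: pd.DataFrame,
    design: DesignInfo,
    exposure_cols: list[str],
) -> FitResult:
    """Weighted least squares with stratified between-PSU linearised variance.

    beta = (X'WX)^-1 X'Wy.  The covariance sandwiches the between-PSU
    variability of the weighted score contributions: within each stratum h
    with n_h PSUs, PSU score totals z_hj are centred and accumulated with the
    (n_h / (n_h - 1)) stratum correction, and the whole meat carries the
    (n - 1)/(n - p) degrees-of-freedom factor standard for cluster-robust
    regression.  With one stratum and each observation its own PSU this
    reduces exactly to the HC1 robust OLS covariance (HC0 times n/(n-p)).
    """
    X = design_matrix.to_numpy(dtype=float)
    y = np.asarray(outcome, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("outcome and design matrix row counts differ")
    w = design.weights
    if n != len(w):
        raise ValueError("design matrix rows must align with the DesignInfo")

    sw = np.sqrt(w)
    XtW = X.T * w
    A = XtW @ X
    rank = np.linalg.matrix_rank(A)
    if rank < p:
        # identify offending columns via pivoted QR on the weighted design
        from scipy.linalg import qr as sqr
        _, r, pv = sqr(X * sw[:, None], pivoting=True, mode="economic")
        bad = [design_matrix.columns[j] for j in pv[rank:]]
        raise np.linalg.LinAlgError(
            f"singular design matrix; collinear column(s): {bad}")
    beta = np.linalg.solve(A, XtW @ y)
    resid = y - X @ beta
    scores = X * (w * resid)[:, None]

    meat = np.zeros((p, p))
    for factor, rows in design.psu_groups():
        z = np.vstack([scores[r].sum(axis=0) for r in rows])
        zc = z - z.mean(axis=0)
        meat += factor * zc.T @ zc
    if n > p:
        meat *= (n - 1) / (n - p)
    Ainv = np.linalg.inv(A)
    cov = Ainv @ meat @ Ainv

    idx = [design_matrix.columns.get_loc(c) for c in exposure_cols]
    return FitResult(beta=beta, cov=cov, df=design.design_df, n=n,
                     exposure_idx=idx, columns=list(design_matrix.columns))


def wald_joint(beta_sub: np.ndarray, cov_sub: np.ndarray, design_df: int,
               n_model_params: int | None = None) -> float:
    """Multivariate Wald test of beta_sub = 0 under the sampling design.

    W = beta' V^-1 beta; F = W/q is referred to F(q, ddf) where the
    denominator df follows the survey-regression residual-df convention
    ddf = d - p + 1 when the full model's parameter count p is supplied, and
    d - q + 1 otherwise (d = #PSUs - #strata).
    """
    b = np.atleast_1d(np.asarray(beta_sub, dtype=float))
    V = np.atleast_2d(np.asarray(cov_sub, dtype=float))
    q = len(b)
    if V.shape != (q, q):
        raise ValueError("covariance must be q x q")
    if design_df < q:
        raise ValueError("design df must be >= number of tested terms")
    try:
        W = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("singular covariance in Wald test") from err
    if W < 0:
        W = 0.0
    ddf = design_df - (q if n_model_params is None else n_model_params) + 1
    ddf = max(ddf, 1)
    p = float(stats.f.sf(W / q, q, ddf))
    return max(p, P_FLOOR)


def pool_rubin(estimates, variances, m: int | None = None,
               complete_df: float = np.inf) -> PooledResult:
    """Rubin's rules with Barnard-Rubin small-sample degrees of freedom.

    T = Wbar + (1 + 1/m) B where Wbar is the mean within-imputation variance
    and B the between-imputation variance of the estimates; ``complete_df``
    is the complete-data (design) degrees of freedom.
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.size == 0:
        raise ValueError("pooling requires at least one fit")
    m = est.size if m is None else m
    if np.all(est == est[0]) and np.all(var == var[0]):
        # identical completed datasets: pooling must reproduce the single
        # fit bit-for-bit, so avoid the (tiny) rounding of the mean
        qbar, wbar, B = est[0], var[0], 0.0
    else:
        qbar = est.mean()
        wbar = var.mean()
        B = est.var(ddof=1) if m > 1 else 0.0
    T = wbar + (1 + 1 / m) * B
    if T <= 0:
        return PooledResult(estimate=float(qbar), se=0.0, df=float(complete_df),
                            p=1.0 if qbar == 0 else P_FLOOR,
                            within_var=float(wbar), between_var=float(B))
    lam = (1 + 1 / m) * B / T
    if lam < 1e-9:
        # numerically no missing information: identical completed datasets
        # must pool to the single-dataset result, so keep the complete df
        lam = 0.0
    if lam <= 0 or m == 1:
        df = float(complete_df)
    else:
        nu_old = (m - 1) / lam ** 2
        if np.isfinite(complete_df):
            nu_obs = (complete_df + 1) / (complete_df + 3) * complete_df * (1 - lam)
            df = nu_old * nu_obs / (nu_old + nu_obs)
        else:
            df = nu_old
    t = qbar / np.sqrt(T)
    p = float(2 * stats.t.sf(abs(t), df)) if np.isfinite(df) \
        else float(2 * stats.norm.sf(abs(t)))
    return PooledResult(estimate=float(qbar), se=float(np.sqrt(T)),
                        df=float(df), p=max(p, P_FLOOR),
                        within_var=float(wbar), between_var=float(B))


def acat_combine(pvals, weights=None) -> float:
    """Aggregated Cauchy association test: combine p-values under dependence.

    T = sum(w_i tan((0.5 - p_i) pi)) / sum(w_i); p = 0.5 - arctan(T)/pi.
    Valid for arbitrarily correlated tests.  p-values of exactly 0 or 1 are
    clipped to [1e-15, 1 - 1e-15] with a warning; values below 1e-15 use the
    Cauchy tail approximation tan((0.5 - p) pi) ~ 1/(p pi) to avoid overflow.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("acat_combine needs at least one p-value")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ((p == 0) | (p == 1)).any():
        warnings.warn("p-values of exactly 0 or 1 clipped for ACAT",
                      stacklevel=2)
        p = np.clip(p, P_FLOOR, 1 - P_FLOOR)
    w = np.full(p.size, 1.0 / p.size) if weights is None \
        else np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("ACAT weights must be positive")
    # cot(p*pi) == tan((0.5 - p)*pi) but avoids cancellation for small p
    with np.errstate(divide="ignore"):
        terms = np.where(p < 0.01, 1.0 / np.tan(p * np.pi),
                         np.tan((0.5 - p) * np.pi))
    T = float((w * terms).sum() / w.sum())
    if T > 0:
        # arctan(1/T)/pi == 0.5 - arctan(T)/pi, stable in the small-p tail
        return float(min(np.arctan(1.0 / T) / np.pi, 1.0))
    return float(min(0.5 - np.arctan(T) / np.pi, 1.0))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _covariate_columns(model: int, stratum: str) -> list[str]:
    cols = list(MODEL1_COVARIATES)
    if model == 2:
        cols += MODEL2_EXTRA
    if stratum in ("female", "male"):
        cols.remove("sex")
    return cols


def build_design_matrix(
    covariates: pd.DataFrame,
    model: int,
    stratum: str = "all",
    selections: dict[str, CovariateSpec] | None = None,
) -> pd.DataFrame:
    """Covariate design (with intercept) for the given model and stratum.

    ``selections`` maps a continuous covariate name to its chosen functional
    form (linear or natural cubic spline); unlisted covariates enter
    linearly.  Categorical covariates are dummy-coded against a reference
    level; single-level columns (e.g. batch when only one batch is present)
    are dropped.
    """
    parts = [pd.Series(1.0, index=covariates.index, name="intercept")]
    for col in _covariate_columns(model, stratum):
        x = covariates[col]
        if col in CATEGORICAL_COVARIATES:
            dummies = pd.get_dummies(x, prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
        elif col == "batch":
            if x.nunique() > 1:
                parts.append((x == 2).astype(float).rename("batch2"))
        else:
            spec = (selections or {}).get(col)
            parts.append(build_covariate_design(x, spec))
    return pd.concat(parts, axis=1)


def _exposure_frame(values: pd.Series, kind: str, name: str) -> pd.DataFrame:
    if kind == "circular":
        s, c = encode_circular(values.to_numpy())
        return pd.DataFrame({f"{name}__sin": s, f"{name}__cos": c},
                            index=values.index)
    return pd.DataFrame({name: values.astype(float)}, index=values.index)


def scan(
    stack: ImputedStack,
    phenotypes: PhenotypeTable,
    covariates: pd.DataFrame,
    design: DesignInfo,
    model: int = 1,
    stratum: str = "all",
    selections: dict[tuple[str, str], CovariateSpec] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the full phenotype x metabolite scan for one model and stratum.

    Returns one row per (phenotype, metabolite) with the pooled estimate and
    SE (linear/binary exposures; circular ones report p-values only), the raw
    pooled p, the FDR-adjusted p (BH across metabolites within the phenotype
    family), and the Model-1 significance flag.

    Metabolites completed by multiple imputation are fitted on each of the m
    datasets and pooled (Rubin for single coefficients, ACAT over the
    per-dataset Wald p-values for circular exposures); metabolites imputed
    once (half-minimum xenobiotics or fully observed) are fitted once.
    ``selections`` optionally maps (metabolite, covariate) to a chosen spline
    form for the continuous covariates.
    """
    if model not in (1, 2):
        raise ValueError("model must be 1 or 2")
    if stratum not in ("all", "female", "male"):
        raise ValueError("stratum must be 'all', 'female' or 'male'")

    idx = stack.datasets[0].index
    cov = covariates.loc[idx]
    mask = np.ones(len(idx), dtype=bool)
    if stratum == "female":
        mask = (cov["sex"] == 0).to_numpy()
    elif stratum == "male":
        mask = (cov["sex"] == 1).to_numpy()
    sub_idx = idx[mask]
    cov = cov.loc[sub_idx]
    sub_design = design.subset(mask)
    d = sub_design.design_df

    kinds = phenotypes.kinds()
    phen_values = phenotypes.values.loc[sub_idx]

    # cache covariate designs per distinct per-metabolite selection profile
    design_cache: dict[tuple, pd.DataFrame] = {}

    def covariate_design_for(met: str) -> pd.DataFrame:
        if selections is None:
            key = ()
            sel = None
        else:
            sel = {c: spec for (m_, c), spec in selections.items() if m_ == met}
            key = tuple(sorted((c, s.form) for c, s in sel.items()))
        if key not in design_cache:
            design_cache[key] = build_design_matrix(cov, model, stratum, sel)
        return design_cache[key]

    records = []
    for phen in phenotypes.values.columns:
        kind = kinds[phen]
        if kind not in ("continuous", "binary", "circular"):
            raise ValueError(f"unknown phenotype kind {kind!r} for {phen!r}")
        expo = _exposure_frame(phen_values[phen], kind, phen)
        expo_cols = list(expo.columns)
        for met in stack.datasets[0].columns:
            base = covariate_design_for(met)
            X = pd.concat([expo, base], axis=1)
            multiply_imputed = stack.provenance.get(met, "none") == "multiple"
            dsets = stack.datasets if multiply_imputed else stack.datasets[:1]

            # survey-regression residual df: d - p + 1 for the fitted model
            d_resid = max(d - X.shape[1] + 1, 1)
            if kind == "circular":
                ps = []
                for dset in dsets:
                    fit = fit_weighted_lm(dset.loc[sub_idx, met].to_numpy(),
                                          X, sub_design, expo_cols)
                    ps.append(wald_joint(fit.exposure_estimates(),
                                         fit.exposure_cov(), d,
                                         n_model_params=X.shape[1]))
                p = acat_combine(ps) if len(ps) > 1 else ps[0]
                est = se = np.nan
            else:
                ests, variances = [], []
                for dset in dsets:
                    fit = fit_weighted_lm(dset.loc[sub_idx, met].to_numpy(),
                                          X, sub_design, expo_cols)
                    ests.append(fit.exposure_estimates()[0])
                    variances.append(fit.exposure_cov()[0, 0])
                pooled = pool_rubin(ests, variances, complete_df=d_resid)
                est, se, p = pooled.estimate, pooled.se, pooled.p
            records.append((phen, kinds[phen], met, model, stratum, est, se, p))

    out = pd.DataFrame(records, columns=[
        "phenotype", "kind", "metabolite", "model", "stratum",
        "estimate", "se", "p"])
    out["p_fdr"] = np.nan
    for phen, grp in out.groupby("phenotype"):
        out.loc[grp.index, "p_fdr"] = bh_adjust(grp["p"].to_numpy())
    out["significant"] = (out["p_fdr"] < alpha) & (out["model"] == 1)
    return out


def ci_containment_check(model1: pd.DataFrame, model2: pd.DataFrame,
                         design_df: float, level: float = 0.95) -> pd.DataFrame:
    """Flag pairs whose Model-2 estimate leaves the Model-1 confidence interval.

    Circular phenotypes are skipped (they carry no effect estimate).
    """
    import logging
    non_circ1 = model1[model1["kind"] != "circular"]
    skipped = model1["kind"].eq("circular").sum()
    if skipped:
        logging.getLogger(__name__).info(
            "ci_containment_check skipped %d circular records "
            "(no effect estimates)", skipped)
    keys = ["phenotype", "metabolite"]
    merged = non_circ1.merge(model2[keys + ["estimate"]], on=keys,
                             suffixes=("_1", "_2"))
    tcrit = stats.t.ppf(0.5 + level / 2, design_df)
    lo = merged["estimate_1"] - tcrit * merged["se"]
    hi = merged["estimate_1"] + tcrit * merged["se"]
    merged["outside_ci"] = (merged["estimate_2"] < lo) | (merged["estimate_2"] > hi)
    return merged[keys + ["estimate_1", "se", "estimate_2", "outside_ci"]]


def _weighted_adjusted_r2(y, X, design: DesignInfo) -> float:
    fit = fit_weighted_lm(y, X, design, exposure_cols=[X.columns[0]])
    w = design.weights
    resid = y - X.to_numpy(dtype=float) @ fit.beta
    ybar = np.average(y, weights=w)
    rss = float((w * resid ** 2).sum())
    tss = float((w * (y - ybar) ** 2).sum())
    n, p = X.shape
    r2 = 1 - rss / tss
    return float(1 - (1 - r2) * (n - 1) / (n - p))


def _weighted_logistic_pseudo_r2(y, X, design: DesignInfo) -> float:
    import statsmodels.api as sm
    Xn = X.to_numpy(dtype=float)
    model = sm.GLM(y, Xn, family=sm.families.Binomial(),
                   var_weights=design.weights)
    res = model.fit()
    mu = res.fittedvalues
    w = design.weights
    ybar = np.average(y, weights=w)
    rss = float((w * (y - mu) ** 2).sum())
    tss = float((w * (y - ybar) ** 2).sum())
    n, p = X.shape
    r2 = 1 - rss / tss
    return float(1 - (1 - r2) * (n - 1) / (n - p))


def biomarker_r2(
    phenotype: pd.Series,
    kind: str,
    metabolite: pd.Series,
    covariates: pd.DataFrame,
    design: DesignInfo,
) -> tuple[float, float, float]:
    """Adjusted R^2 of three nested biomarker models for one phenotype.

    (1) metabolite only, (2) demographic covariates only (age, sex, centre,
    background, BMI), (3) covariates plus metabolite.  Continuous phenotypes
    use weighted linear regression; binary phenotypes use weighted logistic
    regression with a variance-function pseudo-R^2 on the response scale
    (documented approximation).  Circular phenotypes are unsupported.
    """
    if kind == "circular":
        raise ValueError("biomarker R^2 is undefined for circular phenotypes")
    y = phenotype.to_numpy(dtype=float)
    base = build_design_matrix(covariates, model=1, stratum="all")
    base = base.drop(columns=["batch2"], errors="ignore")
    met = metabolite.astype(float).rename("metabolite")
    X_met = pd.concat([pd.Series(1.0, index=covariates.index, name="intercept"),
                       met], axis=1)
    X_both = pd.concat([base, met], axis=1)
    f = _weighted_adjusted_r2 if kind == "continuous" else _weighted_logistic_pseudo_r2
    return (f(y, X_met, design), f(y, base, design), f(y, X_both, design))


def weighted_summary(variable: pd.Series, design: DesignInfo):
    """Design-weighted mean (numeric) or category proportions (categorical)."""
    x = variable.dropna()
    if x.empty:
        raise ValueError("variable has no observed values")
    w = pd.Series(design.weights, index=variable.index).loc[x.index]
    if pd.api.types.is_numeric_dtype(x) and not pd.api.types.is_bool_dtype(x):
        return float(np.average(x, weights=w))
    tot = w.groupby(x).sum()
    return (tot / tot.sum()).to_dict()


def phenotype_effect_correlation(records: pd.DataFrame,
                                 min_shared: int = 3) -> pd.DataFrame:
    """Spearman correlation of squared effect estimates between phenotypes.

    Rows of ``records`` are scan output; circular phenotypes (no estimates)
    are excluded.  Pairs sharing fewer than ``min_shared`` metabolites get
    NaN.
    """
    sub = records[records["kind"] != "circular"]
    wide = sub.pivot_table(index="metabolite", columns="phenotype",
                           values="estimate") ** 2
    phens = list(wide.columns)
    out = pd.DataFrame(np.eye(len(phens)), index=phens, columns=phens)
    for i, a in enumerate(phens):
        for b in phens[i + 1:]:
            pair = wide[[a, b]].dropna()
            if len(pair) < min_shared:
                rho = np.nan
            else:
                rho = stats.spearmanr(pair[a], pair[b]).statistic
            out.loc[a, b] = out.loc[b, a] = rho
    return out
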