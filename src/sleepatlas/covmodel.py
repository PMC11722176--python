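"""Per-(metabolite, covariate) choice between linear and spline adjustment.

Continuous confounders (age, BMI, physical activity, diet) may relate
nonlinearly to metabolite levels.  For each metabolite and each such
covariate, five candidate weighted regressions are fitted — linear, and
natural cubic splines with 1-4 interior knots placed at equal quantiles —
each adjusted for the baseline (Model 1) covariates.  Candidates are scored
by AIC computed from the weighted Gaussian pseudo-log-likelihood (weights
normalised to sum to n), and the least complex model within 2 AIC points of
the minimum is selected: a more complex model must improve AIC by at least 2
points to displace a simpler one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SPLINE_ELIGIBLE = ["age", "bmi", "physact", "diet"]
_COMPLEXITY = {"linear": 0, "spline1": 1, "spline2": 2, "spline3": 3, "spline4": 4}


@dataclass
class CovariateSpec:
    """Functional form for one continuous covariate."""

    covariate: str
    form: str  # linear | spline1..spline4
    knots: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.form not in _COMPLEXITY:
            raise ValueError(f"unknown form {self.form!r}")
        if self.knots != sorted(self.knots) or len(set(self.knots)) != len(self.knots):
            raise ValueError("knots must be strictly increasing")

    @property
    def complexity(self) -> int:
        return _COMPLEXITY[self.form]


@dataclass
class ModelScore:
    spec: CovariateSpec
    aic: float
    n_params: int


def interior_knots(x: np.ndarray, n_knots: int) -> list[float]:
    """Equal-quantile interior knots (1 knot -> median)."""
    qs = np.linspace(0, 1, n_knots + 2)[1:-1]
    return list(np.quantile(x, qs))


def natural_spline_basis(x: pd.Series | np.ndarray, knots: list[float],
                         name: str = "x") -> pd.DataFrame:
    """Natural cubic spline basis with the given interior knots (patsy cr).

    The cr basis places boundary knots at the observed range itself, so K
    interior knots yield K+2 columns spanning the intercept; one column is
    dropped, leaving K+1 spline terms beyond the design's intercept.
    """
    from patsy import dmatrix

    arr = np.asarray(x, dtype=float)
    basis = dmatrix("cr(v, knots=k) - 1", {"v": arr, "k": list(knots)},
                    return_type="dataframe")
    basis.columns = [f"{name}__ns{i + 1}" for i in range(basis.shape[1])]
    if isinstance(x, pd.Series):
        basis.index = x.index
    # drop one column: the cr basis spans the intercept, which the design
    # matrix already carries
    return basis.iloc[:, 1:]


def build_covariate_design(x: pd.Series, spec: CovariateSpec | None) -> pd.DataFrame:
    """Columns for one continuous covariate under a chosen form."""
    if spec is None or spec.form == "linear":
        return x.astype(float).to_frame()
    return natural_spline_basis(x, spec.knots, name=x.name)


def _weighted_gaussian_aic(y: np.ndarray, X: np.ndarray, w: np.ndarray) -> float:
    """AIC = -2 * weighted log-likelihood + 2 * (# mean parameters).

    Weights are normalised to sum to n, so the pseudo-log-likelihood is on
    the scale of an n-observation Gaussian likelihood and AICs are comparable
    across candidate forms.
    """
    n = len(y)
    wn = w * n / w.sum()
    sw = np.sqrt(wn)
    # lstsq tolerates rank deficiency (e.g. a constant covariate column)
    beta = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)[0]
    resid = y - X @ beta
    sigma2 = float((wn * resid ** 2).sum() / n)
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
    return float(-2 * ll + 2 * X.shape[1])


def candidate_scores(
    outcome: pd.Series,
    covariate: pd.Series,
    adjusters: pd.DataFrame,
    weights: np.ndarray,
) -> list[ModelScore]:
    """Score the five candidate forms for one metabolite x covariate.

    Rows with a missing outcome are excluded (all individuals with available
    metabolite levels are used).  ``adjusters`` is the baseline covariate
    design (with intercept) excluding the covariate of interest.  A constant
    covariate yields the linear candidate only, with a warning.
    """
    keep = outcome.notna()
    y = outcome[keep].to_numpy(dtype=float)
    x = covariate[keep]
    A = adjusters.loc[keep.index[keep]].to_numpy(dtype=float)
    w = np.asarray(weights, dtype=float)[keep.to_numpy()]

    if x.nunique() <= 1:
        warnings.warn(f"covariate {covariate.name!r} is constant; "
                      "spline candidates skipped", stacklevel=2)
        forms = [("linear", [])]
    else:
        forms = [("linear", [])] + [
            (f"spline{k}", interior_knots(x.to_numpy(), k)) for k in range(1, 5)]

    scores = []
    for form, knots in forms:
        spec = CovariateSpec(covariate=str(covariate.name), form=form, knots=knots)
        cols = build_covariate_design(x, spec).to_numpy(dtype=float)
        X = np.column_stack([A, cols])
        scores.append(ModelScore(spec=spec,
                                 aic=_weighted_gaussian_aic(y, X, w),
                                 n_params=X.shape[1]))
    return scores


def select_spec(scores: list[ModelScore]) -> CovariateSpec:
    """Least-complex form whose AIC is within 2 points of the minimum.

    Ties at exactly +2 go to the simpler model ("lower by less than 2"
    prefers simpler, so the boundary belongs to the simpler form).
    """
    if not scores:
        raise ValueError("select_spec requires at least one candidate score")
    aic_min = min(s.aic for s in scores)
    eligible = [s for s in scores if s.aic <= aic_min + 2.0]
    return min(eligible, key=lambda s: s.spec.complexity).spec


def select_covariate_forms(
    stack_dataset: pd.DataFrame,
    covariates: pd.DataFrame,
    weights: np.ndarray,
    eligible: list[str] | None = None,
    raw_matrix: pd.DataFrame | None = None,
) -> dict[tuple[str, str], CovariateSpec]:
    """Selection table over all metabolites x eligible continuous covariates.

    Fits use individuals with observed metabolite levels: when the raw
    (pre-imputation) matrix is supplied its missingness pattern masks the
    outcome, otherwise the completed values are used as-is.  Baseline
    adjusters are the Model 1 covariates minus the covariate of interest.
    """
    from .assoc import build_design_matrix  # deferred: circular module link

    eligible = eligible or [c for c in SPLINE_ELIGIBLE if c in covariates.columns]
    base = build_design_matrix(covariates, model=1)
    out: dict[tuple[str, str], CovariateSpec] = {}
    for met in stack_dataset.columns:
        y = stack_dataset[met]
        if raw_matrix is not None and met in raw_matrix.columns:
            y = y.where(raw_matrix[met].notna())
        for covname in eligible:
            drop = [c for c in base.columns if c == covname]
            adjusters = base.drop(columns=drop)
            scores = candidate_scores(y, covariates[covname], adjusters, weights)
            out[(met, covname)] = select_spec(scores)
    return out


def selection_table(selections: dict[tuple[str, str], CovariateSpec]) -> pd.DataFrame:
    """Flatten a selection mapping into a TSV-ready table."""
    rows = [(met, cov, spec.form, ",".join(f"{k:.6g}" for k in spec.knots))
            for (met, cov), spec in selections.items()]
    return pd.DataFrame(rows, columns=["metabolite", "covariate", "form", "knots"])
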