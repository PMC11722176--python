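"""Metabolomics pre-processing: filtering, imputation, normalisation, pairing.

The fixed stage order is: drop metabolites missing in more than a threshold
fraction of either batch -> half-minimum imputation for xenobiotics (missing
values are below-detection-limit, so each is replaced by half the smallest
observed value of that metabolite within its batch) -> chained-equations
multiple imputation with predictive-mean-matching for the remaining
metabolites, run separately per batch, producing m completed datasets ->
rank-based inverse-normal transformation per batch and per completed dataset
-> pairing of the k-th completed batch-1 dataset with the k-th completed
batch-2 dataset by row concatenation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthdata import MetaboliteMatrix

log = logging.getLogger(__name__)

DEFAULT_MISSINGNESS_THRESHOLD = 0.75
DEFAULT_M = 5

# clinical covariates used alongside the metabolites in the chained equations
MICE_COVARIATES = ["age", "sex", "bmi"]


@dataclass
class ImputedStack:
    """m completed participant x metabolite matrices with shared labels.

    ``provenance`` maps each metabolite to its imputation route:
    ``none`` (fully observed), ``half_min`` (xenobiotic, single completion),
    or ``multiple`` (chained equations; differs across the m datasets).
    """

    datasets: list[pd.DataFrame]
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.datasets)

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("ImputedStack needs at least one dataset")
        ref = self.datasets[0]
        for d in self.datasets[1:]:
            if not (d.index.equals(ref.index) and d.columns.equals(ref.columns)):
                raise ValueError("completed datasets must share row/column labels")
        for d in self.datasets:
            if d.isna().any().any():
                raise ValueError("completed datasets must have no missing entries")


def missing_fraction_by_batch(matrix: MetaboliteMatrix) -> pd.DataFrame:
    """Per-metabolite missing fraction within each batch (columns are batches)."""
    out = {}
    for b, idx in matrix.values.groupby(matrix.batch).groups.items():
        sub = matrix.values.loc[idx]
        if len(sub) == 0:
            raise ValueError(f"batch {b} is empty")
        out[b] = sub.isna().mean()
    return pd.DataFrame(out)


def filter_missingness(
    matrix: MetaboliteMatrix,
    threshold: float = DEFAULT_MISSINGNESS_THRESHOLD,
) -> MetaboliteMatrix:
    """Drop metabolites missing in *more than* ``threshold`` of either batch.

    The rule is strict: a metabolite missing in exactly the threshold
    fraction of both batches is retained.  Rows are never dropped.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    frac = missing_fraction_by_batch(matrix)
    kept = frac.index[~(frac > threshold).any(axis=1)]
    dropped = frac.index.difference(kept)
    if len(dropped):
        log.info("filter_missingness dropped %d metabolites: %s",
                 len(dropped), ", ".join(dropped[:10]))
    return MetaboliteMatrix(
        values=matrix.values[kept],
        annotation=matrix.annotation.loc[kept],
        batch=matrix.batch,
        latent=None if matrix.latent is None else matrix.latent[kept],
    )


def impute_half_min(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Half-minimum imputation for xenobiotic metabolites, per batch.

    Each missing xenobiotic entry becomes half the lowest observed value of
    that metabolite within the same batch.  Non-xenobiotic columns pass
    through untouched.
    """
    values = matrix.values.copy()
    xeno = matrix.annotation.index[matrix.annotation["xenobiotic"]]
    for met in xeno.intersection(values.columns):
        for b, idx in values.groupby(matrix.batch).groups.items():
            col = values.loc[idx, met]
            if col.isna().all():
                raise ValueError(
                    f"metabolite {met!r} entirely missing in batch {b}: "
                    "no minimum exists for half-minimum imputation")
            values.loc[idx[col.isna()], met] = 0.5 * col.min()
    return MetaboliteMatrix(values=values, annotation=matrix.annotation,
                            batch=matrix.batch, latent=matrix.latent)


def _mice_one_batch(
    data: pd.DataFrame,
    m: int,
    seed: int,
    n_burn: int,
    max_predictors: int,
) -> list[pd.DataFrame]:
    """Chained-equations PMM on one batch; returns m completed copies."""
    from statsmodels.imputation.mice import MICEData

    incomplete = [c for c in data.columns if data[c].isna().any()]
    if not incomplete:
        return [data.copy() for _ in range(m)]

    work = data.copy()
    # MICEData mangles non-identifier column names; use positional aliases
    alias = {c: f"v{i}" for i, c in enumerate(work.columns)}
    inverse = {v: k for k, v in alias.items()}
    work = work.rename(columns=alias)

    mice = MICEData(work)
    if max_predictors and work.shape[1] - 1 > max_predictors:
        corr = work.corr().abs()
        for col in work.columns:
            if not data[inverse[col]].isna().any():
                continue
            preds = corr[col].drop(col).nlargest(max_predictors).index
            mice.set_imputer(col, formula=" + ".join(preds))

    completed: list[pd.DataFrame] = []
    # MICEData draws from numpy's global RandomState; pin it per dataset so
    # the stack is reproducible for a given seed
    state = np.random.get_state()
    try:
        np.random.seed(seed % (2 ** 31))
        mice.update_all(n_burn)
        for _ in range(m):
            mice.update_all(1)
            done = mice.data.rename(columns=inverse)
            done.index = data.index
            completed.append(done[data.columns].astype(float))
    finally:
        np.random.set_state(state)
    return completed


def impute_multiple(
    matrix: MetaboliteMatrix,
    covariates: pd.DataFrame,
    m: int = DEFAULT_M,
    seed: int = 0,
    n_burn: int = 3,
    max_predictors: int = 30,
) -> ImputedStack:
    """Multiple imputation of non-xenobiotic metabolites, separately per batch.

    Fully conditional specification with predictive-mean-matching draws; the
    imputation model for each metabolite uses the other metabolites plus the
    metabolic covariates present in ``covariates`` (capped at the
    ``max_predictors`` most correlated predictors per target for
    tractability).  Xenobiotic columns must already be complete (half-min);
    they are carried through identically in all m datasets.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    xeno = matrix.annotation["xenobiotic"]
    xeno_cols = list(matrix.annotation.index[xeno].intersection(matrix.values.columns))
    if matrix.values[xeno_cols].isna().any().any():
        raise ValueError("xenobiotic columns must be half-min imputed first")

    covs = [c for c in MICE_COVARIATES if c in covariates.columns]
    per_batch: list[list[pd.DataFrame]] = []
    seeds = np.random.SeedSequence(seed).generate_state(8)
    for bi, (b, idx) in enumerate(sorted(matrix.values.groupby(matrix.batch).groups.items())):
        block = pd.concat(
            [matrix.values.loc[idx], covariates.loc[idx, covs].astype(float)],
            axis=1)
        completed = _mice_one_batch(
            block, m=m, seed=int(seeds[bi]), n_burn=n_burn,
            max_predictors=max_predictors)
        per_batch.append([c[matrix.values.columns] for c in completed])
    per_dataset = [pd.concat([blocks[k] for blocks in per_batch])
                   .reindex(matrix.values.index) for k in range(m)]

    provenance = {}
    for col in matrix.values.columns:
        if col in xeno_cols:
            provenance[col] = "half_min"
        elif matrix.values[col].isna().any():
            provenance[col] = "multiple"
        else:
            provenance[col] = "none"
    datasets = [d[matrix.values.columns] for d in per_dataset]
    return ImputedStack(datasets=datasets, provenance=provenance)


def rank_inverse_normal(values: np.ndarray | pd.Series) -> np.ndarray:
    """Rank-based inverse-normal transform: Phi^-1((rank - 0.5) / n).

    Ties get average ranks (a constant vector maps to all zeros).  The output
    is approximately standard normal whatever the input distribution, and is
    invariant to monotone transforms of the input.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-d vector")
    if arr.size == 0:
        raise ValueError("cannot rank-normalise an empty vector")
    if np.isnan(arr).any():
        raise ValueError("rank_inverse_normal requires a complete vector")
    ranks = stats.rankdata(arr, method="average")
    return stats.norm.ppf((ranks - 0.5) / arr.size)


def rank_normalise_stack(stack: ImputedStack, batch: pd.Series) -> ImputedStack:
    """Apply the inverse-normal transform per batch within each dataset."""
    out = []
    for d in stack.datasets:
        nd = d.copy()
        for b, idx in d.groupby(batch).groups.items():
            for col in d.columns:
                nd.loc[idx, col] = rank_inverse_normal(d.loc[idx, col])
        out.append(nd)
    return ImputedStack(datasets=out, provenance=dict(stack.provenance))


def pair_batches(stack_b1: ImputedStack, stack_b2: ImputedStack) -> ImputedStack:
    """Pair completed datasets across batches: k-th with k-th, rows stacked.

    Columns are aligned by name; participants must be disjoint.  An empty
    second stack (no batch-2 rows) returns the first stack unchanged.
    """
    if stack_b2.datasets[0].shape[0] == 0:
        return stack_b1
    if stack_b1.m != stack_b2.m:
        raise ValueError(f"mismatched m: {stack_b1.m} vs {stack_b2.m}")
    c1 = set(stack_b1.datasets[0].columns)
    if c1 != set(stack_b2.datasets[0].columns):
        raise ValueError("batches must share the same metabolite columns")
    overlap = stack_b1.datasets[0].index.intersection(stack_b2.datasets[0].index)
    if len(overlap):
        raise ValueError(f"participants appear in both batches: {list(overlap[:5])}")
    cols = stack_b1.datasets[0].columns
    datasets = [pd.concat([a, b[cols]]) for a, b in
                zip(stack_b1.datasets, stack_b2.datasets)]
    prov = dict(stack_b1.provenance)
    for k, v in stack_b2.provenance.items():
        if prov.get(k, v) != v:
            prov[k] = "multiple" if "multiple" in (v, prov[k]) else v
        else:
            prov[k] = v
    return ImputedStack(datasets=datasets, provenance=prov)


def preprocess(
    matrix: MetaboliteMatrix,
    covariates: pd.DataFrame,
    m: int = DEFAULT_M,
    threshold: float = DEFAULT_MISSINGNESS_THRESHOLD,
    seed: int = 0,
    max_predictors: int = 30,
) -> ImputedStack:
    """Full pipeline: filter -> half-min -> MI -> per-batch rank-INT -> pair."""
    filtered = filter_missingness(matrix, threshold)
    half = impute_half_min(filtered)
    seeds = np.random.SeedSequence(seed).generate_state(4)

    batches = sorted(half.batch.unique())
    per_batch_stacks = []
    for bi, b in enumerate(batches):
        idx = half.values.index[half.batch == b]
        sub = MetaboliteMatrix(values=half.values.loc[idx],
                               annotation=half.annotation,
                               batch=half.batch.loc[idx])
        stack = impute_multiple(sub, covariates.loc[idx], m=m,
                                seed=int(seeds[bi]),
                                max_predictors=max_predictors)
        stack = rank_normalise_stack(stack, half.batch.loc[idx])
        per_batch_stacks.append(stack)

    combined = per_batch_stacks[0]
    for nxt in per_batch_stacks[1:]:
        combined = pair_batches(combined, nxt)
    # restore the cohort row order
    order = [i for i in matrix.values.index if i in combined.datasets[0].index]
    combined = ImputedStack(
        datasets=[d.loc[order] for d in combined.datasets],
        provenance=combined.provenance)
    return combined
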