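"""Atlas summaries of the scan: incidence, pathway aggregation, similarity.

The Model-1 FDR-significant associations define a binary phenotype x
metabolite incidence matrix.  Aggregating phenotypes by sleep domain and
metabolites by sub- or super-pathway yields a consolidated incidence matrix
(any significant association in the cell) and a weight matrix (how many),
the inputs to the bipartite network metrics.  Domain-level overlap of
significant metabolite sets is measured with the Dice similarity
coefficient.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class IncidenceStructure:
    """Binary incidence plus consolidated domain x pathway matrices.

    ``incidence``: phenotype x metabolite 0/1 (Model-1 FDR-significant).
    ``domain_by_subpathway`` / ``domain_by_superpathway``: count (weight)
    matrices; the binary consolidated incidence is simply ``counts > 0``.
    """

    incidence: pd.DataFrame
    domain_by_subpathway: pd.DataFrame
    domain_by_superpathway: pd.DataFrame

    def consolidated_incidence(self, level: str = "subpathway") -> pd.DataFrame:
        counts = (self.domain_by_subpathway if level == "subpathway"
                  else self.domain_by_superpathway)
        return (counts > 0).astype(int)


def _annotate(records: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    out = records.merge(annotation, left_on="metabolite", right_index=True,
                        how="left")
    missing = out["superpathway"].isna()
    if missing.any():
        warnings.warn(
            f"{out.loc[missing, 'metabolite'].nunique()} metabolites lack "
            "annotation; grouped as 'unannotated'", stacklevel=2)
        for col in ("superpathway", "subpathway"):
            out[col] = out[col].astype(object)
            out.loc[missing, col] = "unannotated"
    return out


def build_incidence(
    records: pd.DataFrame,
    annotation: pd.DataFrame,
    domains: pd.Series,
    alpha: float = 0.05,
) -> IncidenceStructure:
    """Binary and consolidated incidence matrices from Model-1 scan records."""
    m1 = records[records["model"] == 1].copy()
    if m1.empty:
        raise ValueError("build_incidence requires Model 1 records")
    m1["sig"] = (m1["p_fdr"] < alpha).astype(int)
    incidence = m1.pivot_table(index="phenotype", columns="metabolite",
                               values="sig", fill_value=0)
    ann = _annotate(m1, annotation)
    ann["domain"] = ann["phenotype"].map(domains)
    sig = ann[ann["sig"] == 1]
    sub = sig.pivot_table(index="domain", columns="subpathway", values="sig",
                          aggfunc="sum", fill_value=0)
    sup = sig.pivot_table(index="domain", columns="superpathway", values="sig",
                          aggfunc="sum", fill_value=0)
    all_domains = pd.Index(sorted(set(domains[m1["phenotype"].unique()])))
    sub = sub.reindex(all_domains, fill_value=0)
    sup = sup.reindex(all_domains, fill_value=0)
    return IncidenceStructure(incidence=incidence,
                              domain_by_subpathway=sub.astype(int),
                              domain_by_superpathway=sup.astype(int))


def domain_sets(records: pd.DataFrame, domains: pd.Series,
                alpha: float = 0.05) -> dict[str, set[str]]:
    """Per-domain set of metabolites significant for >= 1 phenotype in it."""
    m1 = records[(records["model"] == 1) & (records["p_fdr"] < alpha)]
    out: dict[str, set[str]] = {d: set() for d in domains.unique()}
    for _, row in m1.iterrows():
        out[domains[row["phenotype"]]].add(row["metabolite"])
    return out


def dice(X: set, Y: set) -> float:
    """Dice similarity coefficient DSC = 2|X & Y| / (|X| + |Y|).

    1 means full overlap, 0 no overlap.  Undefined (NaN, with a warning)
    when both sets are empty — not 0.
    """
    if not X and not Y:
        warnings.warn("Dice coefficient of two empty sets is undefined",
                      stacklevel=2)
        return float("nan")
    return 2 * len(set(X) & set(Y)) / (len(X) + len(Y))


def dice_matrix(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Pairwise Dice coefficients between named metabolite sets."""
    names = list(sets)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d = dice(sets[a], sets[b])
            out.loc[a, b] = out.loc[b, a] = d
        if not sets[a]:
            out.loc[a, a] = float("nan")
    return out


def percent_significant(
    records: pd.DataFrame,
    annotation: pd.DataFrame,
    domains: pd.Series,
    level: str = "subpathway",
    alpha: float = 0.05,
    highlight_threshold: float = 25.0,
) -> pd.DataFrame:
    """Share of significant associations per (pathway group, domain) cell.

    percentage = 100 * significant pairs / (metabolites in the group x
    phenotypes in the domain with results).  Groups with no tested
    metabolites are excluded; cells above ``highlight_threshold`` percent are
    flagged.
    """
    if level not in ("subpathway", "superpathway"):
        raise ValueError("level must be 'subpathway' or 'superpathway'")
    m1 = records[records["model"] == 1].copy()
    ann = _annotate(m1, annotation)
    ann["domain"] = ann["phenotype"].map(domains)
    ann["sig"] = (ann["p_fdr"] < alpha).astype(int)

    rows = []
    for (group, domain), cell in ann.groupby([level, "domain"]):
        n_mets = cell["metabolite"].nunique()
        n_phens = cell["phenotype"].nunique()
        n_sig = int(cell["sig"].sum())
        denom = n_mets * n_phens
        if denom == 0:
            continue
        pct = 100.0 * n_sig / denom
        rows.append((group, domain, n_mets, n_phens, n_sig, pct,
                     pct > highlight_threshold))
    return pd.DataFrame(rows, columns=[
        level, "domain", "n_metabolites", "n_phenotypes", "n_significant",
        "percent", "highlighted"])


def top_connected(
    records: pd.DataFrame,
    domains: pd.Series,
    fraction: float = 0.10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Top metabolites by number of significant sleep-phenotype associations.

    Eligibility requires >= 1 significant Model-1 association; the list has
    ceil(fraction x eligible) entries, extended through ties at the cutoff
    count.  Per-domain association counts are attached.
    """
    m1 = records[(records["model"] == 1) & (records["p_fdr"] < alpha)].copy()
    if m1.empty:
        return pd.DataFrame(columns=["metabolite", "n_associations"])
    m1["domain"] = m1["phenotype"].map(domains)
    counts = m1.groupby("metabolite").size().sort_values(ascending=False)
    k = math.ceil(fraction * len(counts))
    cutoff = counts.iloc[k - 1]
    chosen = counts[counts >= cutoff]
    per_domain = m1.pivot_table(index="metabolite", columns="domain",
                                aggfunc="size", fill_value=0)
    out = pd.DataFrame({"n_associations": chosen})
    out = out.join(per_domain).fillna(0).astype(int)
    out.index.name = "metabolite"
    return out.sort_values("n_associations", ascending=False).reset_index()
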