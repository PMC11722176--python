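"""End-to-end pipeline: simulate -> preprocess -> select forms -> scan -> atlas -> network.

Configuration is a YAML file with a ``synthdata`` block (or paths to the four
input tables), model/stratum choices and thresholds.  Every stage writes
tab-delimited outputs with an NA token into a run directory, along with a
manifest recording the package version, a config hash, the master seed and
per-file checksums, so a rerun with an identical config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import DesignInfo, ci_containment_check, scan
from .atlas import (build_incidence, dice_matrix, domain_sets,
                    percent_significant, top_connected)
from .covmodel import select_covariate_forms, selection_table
from .network import BipartiteGraph, fr_layout, properties_by_superpathway
from .preprocess import preprocess
from .synthdata import (CircularEffect, MetaboliteMatrix, PhenotypeTable,
                        SyntheticConfig, simulate, write_tables)

log = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "synthdata", "inputs", "models", "strata", "alpha", "m",
    "missingness_threshold", "top_fraction", "highlight_percent",
    "select_covariates", "seed", "max_predictors",
}


@dataclass
class PipelineConfig:
    """Validated pipeline settings; unknown keys are rejected."""

    synthdata: dict | None = None
    inputs: dict | None = None
    models: list[int] = field(default_factory=lambda: [1, 2])
    strata: list[str] = field(default_factory=lambda: ["all"])
    alpha: float = 0.05
    m: int = 5
    missingness_threshold: float = 0.75
    top_fraction: float = 0.10
    highlight_percent: float = 25.0
    select_covariates: bool = True
    max_predictors: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.synthdata is None) == (self.inputs is None):
            raise ValueError(
                "config needs exactly one of a 'synthdata' block or "
                "an 'inputs' path block")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if any(m not in (1, 2) for m in self.models):
            raise ValueError("models must be a subset of [1, 2]")
        if any(s not in ("all", "female", "male") for s in self.strata):
            raise ValueError("strata must be among all/female/male")
        if self.inputs is not None:
            needed = {"cohort", "phenotypes", "phenotype_meta",
                      "metabolites", "annotation"}
            missing = needed - set(self.inputs)
            if missing:
                raise ValueError(f"inputs block missing keys: {sorted(missing)}")
            for key, path in self.inputs.items():
                if not Path(path).exists():
                    raise FileNotFoundError(f"input table {key!r}: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _build_synth_config(block: dict, seed: int) -> SyntheticConfig:
    block = dict(block)
    effects = {}
    for key, val in (block.pop("effects", {}) or {}).items():
        phen, met = key.split("|")
        if isinstance(val, dict):
            effects[(phen, met)] = CircularEffect(**val)
        else:
            effects[(phen, met)] = float(val)
    block.setdefault("seed", seed)
    return SyntheticConfig(effects=effects, **block)


def _load_inputs(paths: dict):
    cohort = pd.read_csv(paths["cohort"], sep="\t", index_col=0, comment="#")
    phen_values = pd.read_csv(paths["phenotypes"], sep="\t", index_col=0,
                              comment="#")
    phen_meta = pd.read_csv(paths["phenotype_meta"], sep="\t", comment="#")
    values = pd.read_csv(paths["metabolites"], sep="\t", index_col=0,
                         comment="#", na_values=["NA"])
    annotation = pd.read_csv(paths["annotation"], sep="\t", index_col=0,
                             comment="#")
    annotation["xenobiotic"] = annotation["xenobiotic"].astype(bool)
    matrix = MetaboliteMatrix(values=values, annotation=annotation,
                              batch=cohort["batch"])
    return cohort, PhenotypeTable(values=phen_values, meta=phen_meta), matrix


def _write(df: pd.DataFrame, path: Path, header_meta: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(header_meta)
        df.to_csv(fh, sep="\t", na_rep="NA", index=index)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute all stages; returns the run directory.

    Writes per-stage TSVs, a manifest with checksums, and a FAILED marker on
    error (partial outputs are preserved).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta_header = (f"# sleepatlas {__version__} config={config.config_hash()} "
                   f"seed={config.seed}\n")
    manifest: dict = {"version": __version__, "config_hash": config.config_hash(),
                      "seed": config.seed, "stages": [], "files": {}}
    try:
        seeds = np.random.SeedSequence(config.seed).generate_state(8)

        # --- simulate or load ------------------------------------------------
        if config.synthdata is not None:
            synth_cfg = _build_synth_config(config.synthdata, config.seed)
            cohort, phenotypes, matrix, truth = simulate(synth_cfg)
            write_tables(outdir / "inputs", cohort, phenotypes, matrix, synth_cfg)
            manifest["stages"].append("simulate")
        else:
            cohort, phenotypes, matrix = _load_inputs(config.inputs)
        design = DesignInfo.from_cohort(cohort)

        # --- preprocess ------------------------------------------------------
        stack = preprocess(matrix, cohort, m=config.m,
                           threshold=config.missingness_threshold,
                           seed=int(seeds[1]),
                           max_predictors=config.max_predictors)
        _write(stack.datasets[0], outdir / "completed_dataset_1.tsv", meta_header)
        manifest["stages"].append("preprocess")

        # --- covariate form selection ---------------------------------------
        selections = None
        if config.select_covariates:
            keep = stack.datasets[0].index
            selections = select_covariate_forms(
                stack.datasets[0], cohort.loc[keep],
                design.weights, raw_matrix=matrix.values)
            _write(selection_table(selections),
                   outdir / "covariate_forms.tsv", meta_header, index=False)
            manifest["stages"].append("select-covariates")

        # --- scan ------------------------------------------------------------
        all_records = []
        for model in config.models:
            for stratum in config.strata:
                rec = scan(stack, phenotypes, cohort, design, model=model,
                           stratum=stratum, selections=selections,
                           alpha=config.alpha)
                all_records.append(rec)
        records = pd.concat(all_records, ignore_index=True)
        _write(records, outdir / "associations.tsv", meta_header, index=False)
        manifest["stages"].append("scan")

        if set(config.models) >= {1, 2}:
            m1 = records[(records["model"] == 1) & (records["stratum"] == "all")]
            m2 = records[(records["model"] == 2) & (records["stratum"] == "all")]
            cc = ci_containment_check(m1, m2, design.design_df)
            _write(cc, outdir / "model2_ci_check.tsv", meta_header, index=False)

        # --- atlas -----------------------------------------------------------
        domains = phenotypes.domains()
        m1_all = records[(records["model"] == 1) & (records["stratum"] == "all")]
        structure = build_incidence(m1_all, matrix.annotation, domains,
                                    alpha=config.alpha)
        _write(structure.incidence, outdir / "incidence.tsv", meta_header)
        _write(structure.domain_by_subpathway,
               outdir / "domain_by_subpathway_counts.tsv", meta_header)
        _write(structure.domain_by_superpathway,
               outdir / "domain_by_superpathway_counts.tsv", meta_header)
        dsc = dice_matrix(domain_sets(m1_all, domains, alpha=config.alpha))
        _write(dsc, outdir / "dice_domains.tsv", meta_header)
        pct = percent_significant(m1_all, matrix.annotation, domains,
                                  level="subpathway", alpha=config.alpha,
                                  highlight_threshold=config.highlight_percent)
        _write(pct, outdir / "percent_significant_subpathway.tsv",
               meta_header, index=False)
        top = top_connected(m1_all, domains, fraction=config.top_fraction,
                            alpha=config.alpha)
        _write(top, outdir / "top_connected.tsv", meta_header, index=False)
        manifest["stages"].append("atlas")

        # --- network ---------------------------------------------------------
        props = properties_by_superpathway(structure.domain_by_subpathway,
                                           matrix.annotation,
                                           seed=int(seeds[2]) % (2 ** 31))
        _write(props, outdir / "network_properties.tsv", meta_header)
        graph = BipartiteGraph(structure.domain_by_subpathway).drop_empty()
        if graph.n_links:
            layout = fr_layout(graph, seed=int(seeds[3]) % (2 ** 31))
            _write(layout, outdir / "layout.tsv", meta_header)
            edges = graph.weights.stack()
            edges = edges[edges > 0].rename("weight").reset_index()
            edges.columns = ["source", "target", "weight"]
            _write(edges, outdir / "edges.tsv", meta_header, index=False)
        manifest["stages"].append("network")

        for f in sorted(outdir.glob("*.tsv")):
            manifest["files"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()[:16]
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception:
        (outdir / "FAILED").write_text("pipeline failed; partial outputs kept\n")
        raise
    return outdir
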