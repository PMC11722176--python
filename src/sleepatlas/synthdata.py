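"""Synthetic survey-designed cohorts with known sleep-metabolite effects.

The real cohort behind the atlas (a multistage stratified community sample
with unequal selection probabilities, two metabolomics batches profiled years
apart, and below-detection-limit missingness) is access-restricted.  This
module generates cohorts with the same *structure* — strata, PSUs, inverse
inclusion-probability weights, an older batch 2, left-censored xenobiotics,
covariate-dependent missingness elsewhere — and, crucially, with known
ground-truth phenotype->metabolite effects, so that every downstream stage
(imputation, survey-weighted scan, pooling, FDR, network summaries) can be
validated against a truth the restricted data cannot provide.

Phenotypes come in three kinds: continuous (e.g. sleep duration), binary
(dichotomised symptoms), and circular clock-time phenotypes in minutes past
midnight, where 1439 is adjacent to 0.  Circular effects on a metabolite are
parameterised as an amplitude A and phase phi acting through
``A * sin(theta + phi)`` with ``theta = 2*pi*minutes/1440``.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

DOMAINS = ("Duration", "HR", "Insomnia", "EDS", "SDB", "Timing")

# superpathway -> subpathways, cycled over non-xenobiotic metabolites
_PATHWAYS = [
    ("Lipid", ["Phosphatidylethanolamine (PE)", "Primary Bile Acid Metabolism",
               "Pregnenolone Steroids", "Diacylglycerol"]),
    ("Amino Acid", ["Leucine, Isoleucine and Valine Metabolism",
                    "Tyrosine Metabolism", "Glycine, Serine and Threonine Metabolism"]),
    ("Carbohydrate", ["Glycolysis, Gluconeogenesis, and Pyruvate Metabolism",
                      "Amino Sugar Metabolism"]),
    ("Cofactors and Vitamins", ["Nicotinate and Nicotinamide Metabolism",
                                "Vitamin A Metabolism"]),
    ("Peptide", ["Gamma-glutamyl Amino Acid"]),
    ("Nucleotide", ["Purine Metabolism"]),
    ("Energy", ["TCA Cycle"]),
]


@dataclass
class CircularEffect:
    """Sinusoidal effect of a clock-time phenotype: amplitude (SD units) and phase (radians)."""

    amplitude: float
    phase: float = 0.0


@dataclass
class SyntheticConfig:
    """Parameters of the generated cohort, phenotypes and metabolome.

    Defaults describe the standing study conditions: 20 strata x 20 PSUs
    (a multistage community survey samples hundreds of small clusters, and
    design-based variances need clusters to far outnumber model parameters),
    n=1200 participants, 60 endogenous + 8 xenobiotic metabolites, two
    batches (35% in the later, older batch with a +0.4 SD location shift),
    20% left-censoring of xenobiotics, 5% covariate-dependent missingness
    elsewhere, and informative sampling weights driven by age.
    """

    n_strata: int = 20
    psus_per_stratum: int = 20
    n_individuals: int = 1200
    n_metabolites: int = 68
    n_xenobiotic: int = 8
    n_phenotypes_per_domain: dict[str, int] = field(
        default_factory=lambda: {"Duration": 2, "HR": 2, "Insomnia": 2,
                                 "EDS": 1, "SDB": 2, "Timing": 2})
    # (phenotype_name, metabolite_name) -> float beta (linear/binary, SD units)
    # or CircularEffect for Timing phenotypes
    effects: dict[tuple[str, str], float | CircularEffect] = field(default_factory=dict)
    batch_fraction: float = 0.35
    batch_shift: float = 0.4
    missing_rate_xeno: float = 0.20
    missing_rate_other: float = 0.05
    weight_informativeness: float = 1.0
    vonmises_kappa: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_strata", "psus_per_stratum", "n_individuals",
                     "n_metabolites"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.psus_per_stratum < 2:
            raise ValueError(
                "psus_per_stratum must be >= 2: between-PSU variance "
                "estimation needs at least two PSUs per stratum")
        if not 0 <= self.n_xenobiotic <= self.n_metabolites:
            raise ValueError("n_xenobiotic must be in [0, n_metabolites]")
        for name in ("batch_fraction", "missing_rate_xeno", "missing_rate_other"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0, 1]")
        if self.weight_informativeness < 0:
            raise ValueError("weight_informativeness must be >= 0")
        unknown = set(self.n_phenotypes_per_domain) - set(DOMAINS)
        if unknown:
            raise ValueError(f"unknown phenotype domain(s): {sorted(unknown)}")

    @property
    def phenotype_names(self) -> list[str]:
        names = []
        for dom in DOMAINS:
            for k in range(self.n_phenotypes_per_domain.get(dom, 0)):
                names.append(f"{dom.lower()}_{k + 1}")
        return names

    @property
    def metabolite_names(self) -> list[str]:
        n_endo = self.n_metabolites - self.n_xenobiotic
        return [f"met_{i + 1:03d}" for i in range(n_endo)] + \
               [f"xeno_{i + 1:03d}" for i in range(self.n_xenobiotic)]


@dataclass
class PhenotypeTable:
    """Per-participant phenotype values plus per-phenotype metadata.

    ``values`` is participants x phenotypes; ``meta`` has one row per
    phenotype with columns ``domain`` and ``kind`` (continuous | binary |
    circular).  Circular values are minutes past midnight in [0, 1440).
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def kinds(self) -> pd.Series:
        return self.meta.set_index("phenotype")["kind"]

    def domains(self) -> pd.Series:
        return self.meta.set_index("phenotype")["domain"]


@dataclass
class MetaboliteMatrix:
    """Participants x metabolites abundances with annotation and batch labels.

    ``values`` may contain NaN (missing); ``annotation`` has one row per
    metabolite (superpathway, subpathway, xenobiotic flag); ``batch`` is the
    per-participant batch label aligned to ``values.index``.  ``latent`` keeps
    the pre-censoring values when generated with ``keep_latent=True`` so the
    censoring construction can be asserted in tests.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame
    batch: pd.Series
    latent: pd.DataFrame | None = None


@dataclass
class TrueEffects:
    """Ground-truth nonzero effects keyed by (phenotype, metabolite)."""

    effects: dict[tuple[str, str], float | CircularEffect]

    def is_null(self, phenotype: str, metabolite: str) -> bool:
        return (phenotype, metabolite) not in self.effects


def _rng(config: SyntheticConfig, stream: str) -> np.random.Generator:
    # crc32, not hash(): Python salts str hashes per process
    tag = zlib.crc32(stream.encode()) % (2 ** 31)
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag]))


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Draw a stratified multistage cohort with informative sampling weights.

    Participants are allocated to strata and PSUs; batch 2 (a fraction
    ``batch_fraction`` of the sample) has a mean age 8 years above batch 1,
    mirroring the contrast between profiling waves.  Sampling weights are
    inverse inclusion probabilities from a logistic selection model on
    standardised age and a stratum effect; ``weight_informativeness`` scales
    the age coefficient, so 0 makes the weights age-independent.
    """
    rng = _rng(config, "cohort")
    n = config.n_individuals
    stratum = rng.integers(0, config.n_strata, size=n)
    psu_within = rng.integers(0, config.psus_per_stratum, size=n)
    psu = stratum * config.psus_per_stratum + psu_within
    batch = np.where(rng.random(n) < config.batch_fraction, 2, 1)

    age = rng.normal(41.5, 13.0, size=n) + 8.0 * (batch == 2)
    age = np.clip(age, 18, 74)
    z_age = (age - age.mean()) / age.std()

    stratum_eff = rng.normal(0.0, 0.5, size=config.n_strata)
    lin = -0.8 + config.weight_informativeness * 0.6 * z_age + stratum_eff[stratum]
    incl_prob = 1.0 / (1.0 + np.exp(-lin))
    weight = 1.0 / incl_prob

    sex = rng.integers(0, 2, size=n)  # 1 = male
    centre = rng.integers(0, 4, size=n)
    background = rng.integers(0, 7, size=n)
    bmi = np.clip(rng.normal(29.5, 6.1, size=n) + 0.03 * (age - 44), 16, 60)
    alcohol = rng.integers(0, 3, size=n)
    smoking = rng.integers(0, 3, size=n)
    physact = np.clip(rng.lognormal(5.9, 1.0, size=n), 0, 8000)
    diet = rng.normal(47.7, 7.5, size=n)

    return pd.DataFrame({
        "participant_id": [f"P{i + 1:05d}" for i in range(n)],
        "stratum": stratum, "psu": psu, "weight": weight, "batch": batch,
        "age": age, "sex": sex, "centre": centre, "background": background,
        "bmi": bmi, "alcohol": alcohol, "smoking": smoking,
        "physact": physact, "diet": diet,
    }).set_index("participant_id")


def generate_phenotypes(cohort: pd.DataFrame, config: SyntheticConfig) -> PhenotypeTable:
    """Draw sleep phenotypes per domain.

    Non-Timing domains produce continuous phenotypes, every second one
    dichotomised at the latent median (so binary prevalence is ~0.5).  Timing
    phenotypes are circular: von Mises draws (concentration
    ``vonmises_kappa``) around domain-typical clock times, mapped to minutes
    past midnight in [0, 1440).
    """
    rng = _rng(config, "phenotypes")
    n = len(cohort)
    z_age = (cohort["age"] - cohort["age"].mean()) / cohort["age"].std()

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for dom in DOMAINS:
        count = config.n_phenotypes_per_domain.get(dom, 0)
        for k in range(count):
            name = f"{dom.lower()}_{k + 1}"
            if dom == "Timing":
                # bed time ~22:40, wake ~06:30 as typical circular means
                mean_minutes = [22 * 60 + 40, 6 * 60 + 30][k % 2]
                mu = 2 * np.pi * mean_minutes / 1440.0
                theta = rng.vonmises(mu, config.vonmises_kappa, size=n)
                minutes = (theta % (2 * np.pi)) / (2 * np.pi) * 1440.0
                cols[name] = minutes
                meta_rows.append((name, dom, "circular"))
            else:
                latent = 0.3 * z_age.to_numpy() + rng.normal(0, 1, size=n)
                if k % 2 == 1:
                    cols[name] = (latent > np.median(latent)).astype(float)
                    meta_rows.append((name, dom, "binary"))
                else:
                    cols[name] = latent
                    meta_rows.append((name, dom, "continuous"))
    values = pd.DataFrame(cols, index=cohort.index)
    meta = pd.DataFrame(meta_rows, columns=["phenotype", "domain", "kind"])
    return PhenotypeTable(values=values, meta=meta)


def _standardise_exposure(values: np.ndarray, kind: str) -> np.ndarray:
    if kind == "binary":
        return values
    return (values - values.mean()) / values.std()


def generate_metabolome(
    cohort: pd.DataFrame,
    phenotypes: PhenotypeTable,
    config: SyntheticConfig,
    keep_latent: bool = False,
) -> tuple[MetaboliteMatrix, TrueEffects]:
    """Generate abundances with known effects, batch shift and missingness.

    Each metabolite is a unit-variance Gaussian baseline plus small age/BMI
    contributions, the configured phenotype effects (``beta * standardised
    exposure`` for linear/binary, ``A*sin(theta+phi)`` for circular), and a
    ``batch_shift`` location offset for batch 2.  Xenobiotics are then
    left-censored below the batch-specific ``missing_rate_xeno`` quantile
    (below-detection-limit missingness); other metabolites get missing-at-
    random gaps whose probability increases with observed age and BMI,
    averaging ``missing_rate_other``.
    """
    rng = _rng(config, "metabolome")
    n = len(cohort)
    met_names = config.metabolite_names
    kinds = phenotypes.kinds()
    for (ph, met) in config.effects:
        if ph not in phenotypes.values.columns:
            raise ValueError(f"effect references unknown phenotype {ph!r}")
        if met not in met_names:
            raise ValueError(f"effect references unknown metabolite {met!r}")

    z_age = _standardise_exposure(cohort["age"].to_numpy(), "continuous")
    z_bmi = _standardise_exposure(cohort["bmi"].to_numpy(), "continuous")
    batch2 = (cohort["batch"] == 2).to_numpy()

    values = np.empty((n, len(met_names)))
    for j, met in enumerate(met_names):
        y = rng.normal(0.0, 1.0, size=n)
        y += 0.15 * z_age + 0.10 * z_bmi + config.batch_shift * batch2
        for (ph, target), eff in config.effects.items():
            if target != met:
                continue
            x = phenotypes.values[ph].to_numpy()
            if kinds[ph] == "circular":
                if not isinstance(eff, CircularEffect):
                    raise TypeError(
                        f"circular phenotype {ph!r} needs a CircularEffect")
                theta = 2 * np.pi * x / 1440.0
                y += eff.amplitude * np.sin(theta + eff.phase)
            else:
                y += float(eff) * _standardise_exposure(x, kinds[ph])
        values[:, j] = y

    latent = pd.DataFrame(values, index=cohort.index, columns=met_names)
    observed = latent.copy()

    n_endo = config.n_metabolites - config.n_xenobiotic
    batch = cohort["batch"]
    for j, met in enumerate(met_names):
        is_xeno = j >= n_endo
        for b in (1, 2):
            mask = (batch == b).to_numpy()
            if not mask.any():
                continue
            col = latent[met].to_numpy()[mask]
            if is_xeno:
                if config.missing_rate_xeno > 0:
                    cut = np.quantile(col, config.missing_rate_xeno)
                    censored = col < cut
                    idx = latent.index[mask][censored]
                    observed.loc[idx, met] = np.nan
            else:
                if config.missing_rate_other > 0:
                    # MAR: logit depends on observed age/BMI, centred so the
                    # average missingness matches the configured rate
                    lin = 0.8 * z_age[mask] + 0.5 * z_bmi[mask]
                    p = 1 / (1 + np.exp(-(lin - np.log(
                        1 / config.missing_rate_other - 1))))
                    p *= config.missing_rate_other / p.mean()
                    miss = rng.random(mask.sum()) < np.clip(p, 0, 1)
                    idx = latent.index[mask][miss]
                    observed.loc[idx, met] = np.nan

    annotation = _build_annotation(config)
    matrix = MetaboliteMatrix(
        values=observed, annotation=annotation, batch=batch,
        latent=latent if keep_latent else None)
    truth = TrueEffects(effects=dict(config.effects))
    return matrix, truth


def _build_annotation(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    n_endo = config.n_metabolites - config.n_xenobiotic
    flat = [(sup, sub) for sup, subs in _PATHWAYS for sub in subs]
    for i, met in enumerate(config.metabolite_names):
        if i >= n_endo:
            rows.append((met, "Xenobiotics", "Food Component/Plant", True))
        else:
            sup, sub = flat[i % len(flat)]
            rows.append((met, sup, sub, False))
    return pd.DataFrame(
        rows, columns=["metabolite", "superpathway", "subpathway", "xenobiotic"]
    ).set_index("metabolite")


def simulate(config: SyntheticConfig, keep_latent: bool = False):
    """Run all three generators; returns (cohort, phenotypes, matrix, truth)."""
    cohort = generate_cohort(config)
    phenotypes = generate_phenotypes(cohort, config)
    matrix, truth = generate_metabolome(cohort, phenotypes, config,
                                        keep_latent=keep_latent)
    return cohort, phenotypes, matrix, truth


def sample_informative_population(
    n_population: int,
    n_sample: int,
    beta0: float = 0.3,
    beta_mod: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Finite population with an age-modified slope and age-driven selection.

    The metabolite follows ``y = (beta0 + beta_mod * z_age) * x + noise``, so
    the census (population OLS) slope is ~``beta0`` while a sample that
    over-represents older individuals has a larger unweighted slope.
    Selection probability is logistic in ``z_age``; inverse-probability
    weights are attached.  Returns the drawn sample (with stratum/psu/weight
    columns ready for a survey fit) and the census slope computed on the full
    population — the estimand a design-consistent estimator should recover.
    """
    rng = np.random.default_rng(seed)
    z_age = rng.normal(size=n_population)
    x = rng.normal(size=n_population)
    y = (beta0 + beta_mod * z_age) * x + rng.normal(size=n_population)
    X = np.column_stack([np.ones(n_population), x])
    census_slope = float(np.linalg.lstsq(X, y, rcond=None)[0][1])

    lin = 1.2 * z_age
    p = 1 / (1 + np.exp(-lin))
    p *= n_sample / p.sum()
    p = np.clip(p, 1e-6, 1)
    take = rng.random(n_population) < p
    sample = pd.DataFrame({
        "x": x[take], "y": y[take], "weight": 1.0 / p[take],
        "stratum": np.zeros(take.sum(), dtype=int),
        "psu": np.arange(take.sum()),
    })
    return sample, census_slope


def write_tables(outdir: str | Path, cohort: pd.DataFrame,
                 phenotypes: PhenotypeTable, matrix: MetaboliteMatrix,
                 config: SyntheticConfig) -> None:
    """Write the four standard tab-delimited input tables plus metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(outdir / "cohort.tsv", sep="\t", na_rep="NA")
    phen = phenotypes.values.copy()
    phen.to_csv(outdir / "phenotypes.tsv", sep="\t", na_rep="NA")
    phenotypes.meta.to_csv(outdir / "phenotype_meta.tsv", sep="\t", index=False)
    matrix.values.to_csv(outdir / "metabolites.tsv", sep="\t", na_rep="NA")
    matrix.annotation.to_csv(outdir / "annotation.tsv", sep="\t")
    cfg = dataclasses.asdict(config)
    cfg["effects"] = {f"{ph}|{met}": (dataclasses.asdict(e)
                      if isinstance(e, CircularEffect) else e)
                      for (ph, met), e in config.effects.items()}
    import json
    (outdir / "simulation_meta.json").write_text(
        json.dumps(cfg, indent=2, default=str))
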