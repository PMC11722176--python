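import numpy as np
import pandas as pd
import pytest

from sleepatlas.assoc import DesignInfo
from sleepatlas.synthdata import (MetaboliteMatrix, SyntheticConfig, simulate)


@pytest.fixture(scope="session")
def small_sim():
    """A small complete simulation with one known linear effect."""
    cfg = SyntheticConfig(
        n_individuals=500, n_metabolites=15, n_xenobiotic=2,
        n_phenotypes_per_domain={"Duration": 1, "HR": 1, "Timing": 1},
        effects={("duration_1", "met_001"): 0.5},
        missing_rate_other=0.0, missing_rate_xeno=0.0, seed=11)
    cohort, phen, mat, truth = simulate(cfg)
    return cfg, cohort, phen, mat, truth


@pytest.fixture
def simple_design():
    """Equal weights, one stratum, each observation its own PSU (n=40)."""
    n = 40
    return DesignInfo(strata=np.zeros(n, dtype=int),
                      psus=np.arange(n),
                      weights=np.ones(n))


def make_matrix(values: pd.DataFrame, batch, xeno=None) -> MetaboliteMatrix:
    """Hand-built MetaboliteMatrix with a minimal annotation table."""
    mets = list(values.columns)
    xeno = set(xeno or [])
    ann = pd.DataFrame({
        "metabolite": mets,
        "superpathway": ["Xenobiotics" if m in xeno else "Lipid" for m in mets],
        "subpathway": ["Food Component/Plant" if m in xeno else "Sterol"
                       for m in mets],
        "xenobiotic": [m in xeno for m in mets],
    }).set_index("metabolite")
    return MetaboliteMatrix(values=values, annotation=ann,
                            batch=pd.Series(batch, index=values.index))
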