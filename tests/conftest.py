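import logging

import numpy as np
import pandas as pd
import pytest

from famqtl import compute_kinship
from famqtl.pheno_prep import adjust_medication, residualize
from famqtl.synthetic_data import scaled_config, simulate_study

logging.getLogger("famqtl").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_study():
    """A 20-family scaled simulation shared across tests (read-only)."""
    return simulate_study(scaled_config(20), seed=11)


@pytest.fixture(scope="session")
def small_inputs(small_study):
    """(trait series, kinship, minor-dosage frame, MAF series) for it."""
    ph = adjust_medication(small_study.phenotypes)
    resid = residualize(ph, "sbp_adj")
    idx = pd.MultiIndex.from_frame(ph[["family_id", "individual_id"]])
    trait = pd.Series(resid.values, index=idx, name="sbp")
    kin = compute_kinship(small_study.pedigrees)
    gm = small_study.genotypes
    dose, maf = gm.minor_dosage()
    gidx = pd.MultiIndex.from_tuples(gm.samples, names=["family_id", "individual_id"])
    dose_df = pd.DataFrame(dose, index=gidx, columns=gm.markers["marker_id"])
    maf_s = pd.Series(maf, index=gm.markers["marker_id"].to_numpy())
    return trait, kin, dose_df, maf_s


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
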