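import logging

import numpy as np
import pytest

import heteropool as hp
from heteropool import trial_models as tm

logging.getLogger("heteropool").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def desk():
    """One sparse desk-scale MET shared across read-only tests."""
    return hp.desk_preset(seed=11)


@pytest.fixture(scope="session")
def desk_fits(desk):
    """Stage-1 additive+SCA fits for every site of the shared desk MET."""
    H = tm.build_hybrid_additive_design(
        desk.plan, parents=list(desk.panel.genotypes.individual_ids))
    spec = tm.TrialModelSpec(genetic="additive+sca", residual="iid")
    return tm.fit_all_sites(desk.pheno, spec, H=H), H


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
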