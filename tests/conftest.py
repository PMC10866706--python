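"""Shared fixtures: synthetic datasets and (expensive) fitted models.

The heavy fixtures are session-scoped so the recovery, uncertainty and
allosteric-mapping checks all reuse a single noiseless fit and a single
10-member Monte-Carlo ensemble.
"""

from __future__ import annotations

import numpy as np
import pytest

from ddpca import synthetic_data as sd
from ddpca import thermo_model as tm
from ddpca import uncertainty as un

TRUTH_SEED = 3
DATA_SEED = 11
FIT_SEED = 5
MASTER_SEED = 51


@pytest.fixture(scope="session")
def truth40():
    """40-position test preset of the synthetic study."""
    return sd.sample_truth(n_positions=40, seed=TRUTH_SEED)


@pytest.fixture(scope="session")
def library40(truth40):
    return sd.design_library(truth40)


@pytest.fixture(scope="session")
def noiseless_fit(truth40, library40):
    """Noiseless, no-resampling fit of the 40-position preset.

    Early stopping is disabled for this degenerate-noise benchmark (see
    docs/methods.md); all noisy paths use the default stopping rule.
    """
    data = sd.simulate_fitness(truth40, library40, sigma=0.0, seed=DATA_SEED)
    config = tm.TrainingConfig(seed=FIT_SEED, max_epochs=1000,
                               early_stop_wt_sd=0.0)
    split = tm.split_data(data.observations, config)
    model, log = tm.fit_model(data.observations, split, config)
    return {"truth": truth40, "data": data, "split": split,
            "model": model, "log": log, "config": config}


@pytest.fixture(scope="session")
def noisy_ensemble(truth40, library40):
    """sigma=0.1 dataset with a 10-member MC ensemble at reduced epochs."""
    data = sd.simulate_fitness(truth40, library40, sigma=0.1, seed=DATA_SEED)
    config = tm.TrainingConfig(seed=FIT_SEED, max_epochs=400)
    ensemble = un.mc_ensemble(data.observations, config, n_models=10,
                              master_seed=MASTER_SEED)
    estimates = un.summarize_energies(ensemble)
    return {"truth": truth40, "data": data, "ensemble": ensemble,
            "estimates": estimates, "config": config}


@pytest.fixture(scope="session")
def small_dataset():
    """12-position, single-partner dataset for fast trainer checks."""
    truth = sd.sample_truth(n_positions=12, partners=("RAF1",), seed=8)
    library = sd.design_library(truth, backgrounds_per_single=6)
    data = sd.simulate_fitness(truth, library, sigma=0.1, seed=2)
    return {"truth": truth, "observations": data.observations}


def true_energy_map(truth) -> dict:
    out = {("folding", s): v for s, v in truth.ddgf.items()}
    for p in truth.partners:
        out.update({(f"binding:{p}", s): v for s, v in truth.ddgb[p].items()})
    return out


def recovery_arrays(truth, estimates):
    tmap = true_energy_map(truth)
    t = np.array([tmap[(e.trait, e.variant)] for e in estimates])
    f = np.array([e.mean_ddg for e in estimates])
    return t, f
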