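import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from trialdyn import (EpochSet, baseline_correct, generate_dataset,
                      preset_biphasic)

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_epochs(voltages, subjects=None, conditions=None, electrodes=None,
                times=None, items=None):
    """Build a valid EpochSet around a raw (trial, electrode, sample) array."""
    voltages = np.asarray(voltages, dtype=float)
    n_tr, n_el, n_sm = voltages.shape
    trials = pd.DataFrame({
        "subject": subjects if subjects is not None else ["S1"] * n_tr,
        "item": items if items is not None else [f"I{i}" for i in range(n_tr)],
        "condition": conditions if conditions is not None else ["A"] * n_tr,
    })
    return EpochSet(
        trials=trials,
        electrodes=electrodes if electrodes is not None else
        [f"E{j}" for j in range(n_el)],
        times=times if times is not None else np.arange(n_sm, dtype=float),
        voltages=voltages,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230620)


@pytest.fixture(scope="session")
def small_biphasic():
    """Baseline-corrected 4-subject x 24-item biphasic simulation + truth."""
    cfg = preset_biphasic(n_subjects=4, n_items=24, seed=7)
    epochs, truth = generate_dataset(cfg)
    return baseline_correct(epochs), truth, cfg


@pytest.fixture
def random_epochs(rng):
    """Small random EpochSet with realistic metadata, for oracle tests."""
    n_subj, n_items, n_el, n_sm = 3, 8, 2, 25
    subjects = np.repeat([f"S{i}" for i in range(n_subj)], n_items)
    items = np.tile([f"I{i}" for i in range(n_items)], n_subj)
    conds = np.where(np.arange(n_subj * n_items) % 2 == 0, "A", "B")
    volts = rng.normal(0, 5, (n_subj * n_items, n_el, n_sm))
    return make_epochs(volts, subjects=subjects, conditions=conds,
                       electrodes=["Cz", "Pz"],
                       times=np.linspace(-200, 1000, n_sm), items=items)
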