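import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import kinomescreen as ks

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_config() -> ks.SimulationConfig:
    return ks.SimulationConfig(
        n_samples=4,
        group_labels=("tumor", "tumor", "healthy", "healthy"),
        n_peptides=12,
        n_kinases=4,
        timepoints=tuple(range(40, 1841, 120)),
        planted_fold_changes={"KIN01": ("tumor", "healthy", 4.0)},
        drug_target_effects={"DRUG01": ("KIN01", 4.0), "DRUG02": ("KIN02", 0.0)},
        orphan_fraction=0.1,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return ks.generate_kinome_dataset(tiny_config)


@pytest.fixture(scope="session")
def tiny_activity(tiny_dataset):
    signals, annotation, truth = tiny_dataset
    return ks.preprocess(signals).activity


def make_signal_table(curves: dict, times) -> pd.DataFrame:
    """Long signal table from {(sample, peptide, replicate): f(t) or array}."""
    rows = []
    times = np.asarray(times, dtype=float)
    for (sample, peptide, rep), f in curves.items():
        vals = f(times) if callable(f) else np.asarray(f, dtype=float)
        for t, v in zip(times, vals):
            rows.append((sample, peptide, rep, t, v))
    return pd.DataFrame(
        rows, columns=["sample_id", "peptide_id", "replicate", "time_s", "signal_lux"]
    )
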