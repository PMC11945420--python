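import numpy as np
import pandas as pd
import pytest

import mronjpred as mp


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic report database with planted signals."""
    cfg = mp.SimulationConfig(
        n_drugs=20, n_reports=20_000, target_event_rate=0.01,
        planted_positive_drugs={"POS_A": 8.0, "POS_B": 5.0},
        planted_negative_drugs={"NEG_A": 0.2},
        duplicate_fraction=0.05, date_inconsistency_fraction=0.1, seed=7)
    return cfg, mp.generate_report_tables(cfg)


@pytest.fixture(scope="session")
def analysis_table(small_sim):
    _, sim = small_sim
    return mp.run_etl(sim.drug, sim.therapy, sim.demographic, sim.reaction)


@pytest.fixture()
def tiny_analysis():
    """Hand-built 10-row analysis table: drug X has 3 target + 2 other rows,
    the rest 1 target + 4 other."""
    rows = ([("X", True)] * 3 + [("X", False)] * 2
            + [("Y", True)] + [("Y", False)] * 2 + [("Z", False)] * 2)
    return pd.DataFrame(rows, columns=["drug_name", "is_target_event"])


@pytest.fixture(scope="session")
def descriptor_sim():
    cfg = mp.DescriptorSimConfig(
        n_positive=60, n_negative=108, n_noise_features=10,
        n_collinear_duplicates=2, n_missing_columns=2, seed=3)
    return cfg, mp.generate_descriptor_matrix(cfg)


def random_confusion_matrices(n, seed, max_count=200):
    rng = np.random.default_rng(seed)
    return [tuple(int(x) for x in rng.integers(0, max_count, 4))
            for _ in range(n)]
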