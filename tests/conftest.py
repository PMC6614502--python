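import numpy as np
import pandas as pd
import pytest

from blankqc import BatchConditioning, generate_batch, plasma_like
from blankqc.io import PeakTable, annotate_sequence


def make_table(classes, area, rt=None, width=None, detected=None,
               mz=None, rt_median=None):
    """Build a PeakTable from an ordered class list and matrices."""
    area = np.asarray(area, dtype=float)
    n_feat, n_inj = area.shape
    assert n_inj == len(classes)
    seq = annotate_sequence(pd.DataFrame({
        "run_order": np.arange(1, n_inj + 1),
        "sample_class": list(classes),
    }))
    fids = pd.Index([f"F{i + 1:03d}" for i in range(n_feat)], name="feature_id")
    cols = seq.index

    def mat(x, default, dtype=float):
        if x is None:
            x = np.full((n_feat, n_inj), default)
        return pd.DataFrame(np.asarray(x), index=fids, columns=cols).astype(dtype)

    features = pd.DataFrame({
        "mz": mz if mz is not None else np.linspace(100, 900, n_feat),
        "rt_median": rt_median if rt_median is not None else np.linspace(0.5, 6, n_feat),
    }, index=fids)
    return PeakTable(
        features=features, sequence=seq,
        area=mat(area, 0.0),
        rt=mat(rt, 1.0),
        width=mat(width, 0.1),
        detected=mat(detected, True, bool) if detected is not None else mat(area > 0, True, bool),
    ).validate()


def small_plasma_config(seed=3, noise_rsd=0.05, drift=0.15):
    sim = plasma_like(seed=seed)
    sim.n_features_by_class = {
        "informative_stable": 4,
        "informative_cluster1": 20,
        "informative_cluster2": 16,
        "contaminant": 20,
        "carryover_1": 4,
        "carryover_2": 2,
        "carryover_3": 4,
    }
    sim.n_cycles_intense = 4
    sim.n_cycles_mild = 4
    sim.noise_rsd = noise_rsd
    sim.drift_amplitude = drift
    return sim


@pytest.fixture(scope="session")
def small_batch():
    """Small plasma-style batch (70 features, 4+4 cycles, 5% noise)."""
    sim = small_plasma_config()
    table, truth = generate_batch(sim)
    return table, truth, sim


@pytest.fixture(scope="session")
def noisefree_batch():
    """Same design without noise or drift: exact recovery expected."""
    sim = small_plasma_config(noise_rsd=0.0, drift=0.0)
    table, truth = generate_batch(sim)
    return table, truth, sim


@pytest.fixture(scope="session")
def small_results(small_batch):
    """Fitted model on the small batch with a reduced SVR grid."""
    table, truth, sim = small_batch
    model = BatchConditioning.from_simulation(sim)
    model.config.svrc.n_eps, model.config.svrc.n_gamma = 4, 9
    return model.fit(m=100, seed=1)
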