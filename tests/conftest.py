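import numpy as np
import pandas as pd
import pytest

from genescout import io as gio
from genescout import simulate
from genescout._nbinom import nb_rvs


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulated dataset shared across tests."""
    cfg = simulate.SimulationConfig(seed=7)
    return cfg, simulate.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory):
    """Desk-scale fixture written to disk (500 genes, 6 timepoints)."""
    d = tmp_path_factory.mktemp("fixture")
    cfg = simulate.small_config(seed=3)
    simulate.write_fixture(simulate.simulate_dataset(cfg), d)
    return d


def two_group_counts(n_genes, n_per=6, de_idx=None, fold=4.0, alpha=0.1,
                     seed=0, base_log_mean=np.log(80.0)):
    """Single-batch two-condition NB counts with optional planted fold change."""
    rng = np.random.Generator(np.random.PCG64(seed))
    mu = rng.lognormal(base_log_mean, 1.0, n_genes)
    foldvec = np.ones(n_genes)
    if de_idx is not None:
        foldvec[np.asarray(de_idx)] = fold
    sample_ids = [f"E_{i}" for i in range(n_per)] + [f"P_{i}" for i in range(n_per)]
    counts = np.empty((n_genes, 2 * n_per), dtype=np.int64)
    for j in range(n_per):
        counts[:, j] = nb_rvs(rng, mu, alpha)
    for j in range(n_per):
        counts[:, n_per + j] = nb_rvs(rng, mu * foldvec, alpha)
    cm = gio.CountMatrix([f"g{i}" for i in range(n_genes)], sample_ids, counts)
    meta = gio.SampleMetadata(pd.DataFrame({
        "sample_id": sample_ids,
        "batch": ["B1"] * (2 * n_per),
        "timepoint": [f"E1{i}" for i in range(n_per)] + [f"P{i}" for i in range(n_per)],
        "condition": ["embryonic"] * n_per + ["postnatal"] * n_per,
        "replicate": [1] * (2 * n_per),
    }))
    return cm, meta


def two_batch_counts(n_genes=2000, batch_factor=2.5, disp_factor=1.0,
                     cond_fold=1.0, alpha=0.1, seed=0, n_per_cell=3):
    """Two batches x two conditions, n_per_cell samples per cell."""
    rng = np.random.Generator(np.random.PCG64(seed))
    mu = rng.lognormal(np.log(80.0), 1.0, n_genes)
    rows, cols = [], []
    counts = np.empty((n_genes, 4 * n_per_cell), dtype=np.int64)
    j = 0
    for b, (bf, df_) in enumerate([(1.0, 1.0), (batch_factor, disp_factor)]):
        for cond, cf in [("embryonic", 1.0), ("postnatal", cond_fold)]:
            for r in range(n_per_cell):
                sid = f"B{b+1}_{cond[:1]}{r}"
                cols.append(sid)
                rows.append({"sample_id": sid, "batch": f"B{b+1}",
                             "timepoint": ("E1" if cond == "embryonic" else "P1") + str(r),
                             "condition": cond, "replicate": r + 1})
                counts[:, j] = nb_rvs(rng, mu * bf * cf, alpha * df_)
                j += 1
    cm = gio.CountMatrix([f"g{i}" for i in range(n_genes)], cols, counts)
    meta = gio.SampleMetadata(pd.DataFrame(rows))
    return cm, meta
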