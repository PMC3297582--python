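import numpy as np
import pytest

from upticksim.network import build_network
from upticksim.params import ModelParams, strain_preset
from upticksim.ssa import run_ensemble


@pytest.fixture(scope="session")
def default_params():
    return ModelParams()


@pytest.fixture(scope="session")
def small_ensembles(default_params):
    """300-run ensembles of the key strains, shared across unit tests."""
    out = {}
    for label in ("wt", "d_rok"):
        net = build_network(strain_preset(label), default_params)
        out[label] = run_ensemble(net, 300, 6.0, base_seed=2000)
    return out


def fake_ensemble(tx_times_per_run, t_end, mrna=None, n_promoters=1,
                  label="fake", snapshot_dt=0.05):
    """Hand-built EnsembleResult for exercising the statistics layer."""
    from upticksim.ssa import EnsembleResult

    n_runs = len(tx_times_per_run)
    grid = np.arange(0.0, t_end + snapshot_dt / 2, snapshot_dt)
    if mrna is None:
        mrna = np.zeros((n_runs, n_promoters, len(grid)), dtype=np.int64)
    tx = [
        [np.asarray(run, dtype=float)] if n_promoters == 1 else
        [np.asarray(p, dtype=float) for p in run]
        for run in tx_times_per_run
    ]
    return EnsembleResult(
        n_runs=n_runs, base_seed=0, strain_label=label, t_end=t_end,
        grid=grid, mrna_counts=mrna, tx_times=tx, n_promoters=n_promoters,
    )
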