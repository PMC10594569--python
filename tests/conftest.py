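import numpy as np
import pandas as pd
import pytest

import qminet as q


@pytest.fixture(scope="session")
def small_experiment():
    """A small planted starve/refeed experiment shared across tests.

    30 interactions, 4 matched replicates, one planted 8-member module with a
    +0.5 log2 response to refeeding.
    """
    cfg = q.SimulationConfig(
        n_interactions=30,
        conditions=("starved", "refed"),
        n_biological_replicates=4,
        beads_per_well=(60, 80),
        planted_modules=(
            q.PlantedModule("response", tuple(range(8)), {"refed": 0.5}),
        ),
        seed=11,
    )
    return cfg, q.simulate_experiment(cfg)


@pytest.fixture()
def bead_csv(tmp_path):
    """Minimal hand-written bead event CSV (3 events, one interaction)."""
    path = tmp_path / "beads.csv"
    path.write_text(
        "sample_id,well_id,batch_id,ip,probe,fluorescence\n"
        "s1,w1,b1,AKT,MTOR,100\n"
        "s1,w1,b1,AKT,MTOR,200\n"
        "s1,w1,b1,AKT,MTOR,300\n"
    )
    return path


def random_mfi_matrix(rng, n_interactions=12, n_samples=10, scale="log2"):
    values = pd.DataFrame(
        rng.normal(10.0, 1.0, size=(n_interactions, n_samples)),
        index=[f"P{i}_Q{i}" for i in range(n_interactions)],
        columns=[f"s{j:02d}" for j in range(n_samples)],
    )
    if scale == "linear":
        values = np.exp2(values)
    return q.MFIMatrix(values, scale)
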