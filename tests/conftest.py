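import numpy as np
import pandas as pd
import pytest

from structcov.synthetic_data import paper_scenario, simulate_cohort
from structcov.volumes_io import VolumeTable, default_hierarchy


def make_volume_table(
    n_per_cell=(3, 3, 3, 3), regions=("r1", "r2", "r3"), seed=0, scale=10.0
) -> VolumeTable:
    """Small random VolumeTable; cells ordered control_M, control_F, treated_M, treated_F."""
    rng = np.random.default_rng(seed)
    cells = ["control_M", "control_F", "treated_M", "treated_F"]
    rows, ids = [], []
    for cell, n in zip(cells, n_per_cell):
        group, sex = cell.rsplit("_", 1)
        for i in range(n):
            ids.append(f"{cell}_{i}")
            rows.append({"sex": sex, "group": group})
    design = pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"))
    volumes = pd.DataFrame(
        scale + rng.random((len(ids), len(regions))),
        index=design.index,
        columns=list(regions),
    )
    return VolumeTable(volumes=volumes, design=design)


@pytest.fixture(scope="session")
def hierarchy159():
    return default_hierarchy()


@pytest.fixture(scope="session")
def preset_config():
    return paper_scenario(seed=0)


@pytest.fixture(scope="session")
def preset_cohort(preset_config):
    """One preset cohort shared by read-only tests."""
    return simulate_cohort(preset_config, seed=11)


@pytest.fixture()
def small_vt():
    return make_volume_table()


def write_tables(tmp_path, volumes: pd.DataFrame, design: pd.DataFrame):
    vpath = tmp_path / "volumes.csv"
    dpath = tmp_path / "design.csv"
    volumes.to_csv(vpath, index_label="subject_id")
    design.to_csv(dpath, index_label="subject_id")
    return vpath, dpath
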