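import numpy as np
import pytest

from famburden.burden import compute_gbs
from famburden.datasets import core_family
from famburden.simulate import SimulationConfig, simulate_family


@pytest.fixture(scope="session")
def core():
    return core_family()


@pytest.fixture(scope="session")
def sim_family():
    """A clean (no missingness, no injected errors) synthetic family."""
    return simulate_family(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def sim_burden(sim_family):
    return compute_gbs(sim_family.genotypes, sim_family.panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def write_ped(path, rows):
    """rows: (fid, iid, father, mother, sex, pheno) tuples."""
    path.write_text("\n".join("\t".join(map(str, r)) for r in rows) + "\n")
    return path


@pytest.fixture()
def core_family_ped(tmp_path):
    """Seven-member three-generation PED file mirroring the worked example."""
    rows = [
        ("FAM1", "J-003", 0, 0, 2, 2),
        ("FAM1", "J-005", 0, 0, 1, 1),
        ("FAM1", "J-006", 0, 0, 2, 1),
        ("FAM1", "J-011", "J-005", "J-006", 1, 1),
        ("FAM1", "J-025", 0, "J-003", 2, 1),
        ("FAM1", "J-012", "J-011", "J-025", 1, 1),
        ("FAM1", "J-017", "J-011", "J-025", 1, 1),
    ]
    return write_ped(tmp_path / "core.ped", rows)
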