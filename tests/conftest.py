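import pytest

from motionbids.synthgen import generate_dataset


@pytest.fixture(scope="session")
def scenario_trees(tmp_path_factory):
    """One generated dataset tree per scenario, shared read-only across the
    session; tests that mutate a tree must copy it first."""
    trees = {}
    for scenario in ("fig1_gait", "spotrotation_like", "dualtask_like",
                     "imu_plus_optical"):
        root = tmp_path_factory.mktemp(scenario)
        generate_dataset(root, scenario, seed=7)
        trees[scenario] = root
    return trees


@pytest.fixture()
def fig1_tree(scenario_trees):
    return scenario_trees["fig1_gait"]


@pytest.fixture()
def spotrotation_tree(scenario_trees):
    return scenario_trees["spotrotation_like"]
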