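import numpy as np
import pytest

from procad.genome import ArmTable, ChromArm, make_bins
from procad.simulate import CnvEvent, SimConfig, simulate_cohort, toy_arm_table


@pytest.fixture(scope="session")
def toy_arms():
    return toy_arm_table()  # 4 chromosomes x (p + q) arms of 10 Mb


@pytest.fixture(scope="session")
def toy_grid(toy_arms):
    return make_bins(toy_arms, 200_000)  # 50 bins per arm, 400 total


@pytest.fixture(scope="session")
def two_chrom_arms():
    entries = (
        ChromArm("chr1", "p", 0, 1_000_000),
        ChromArm("chr1", "q", 1_000_000, 2_100_000),
        ChromArm("chr2", "p", 0, 1_000_000),
        ChromArm("chr2", "q", 1_000_000, 2_000_000),
    )
    return ArmTable(entries=entries, assembly_label="toy2")


@pytest.fixture(scope="session")
def null_cohort(toy_arms):
    """9 controls + 4 flat cases (no events), modest depth for speed."""
    cfg = SimConfig(
        rng_seed=11,
        n_controls=9,
        n_cases=4,
        arm_table=toy_arms,
        mean_read_pairs=2_000_000,
        events=[[] for _ in range(4)],
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def event_cohort(toy_arms):
    """9 controls + 6 cases, one single-copy gain each at f = 0.4."""
    names = [e.name for e in toy_arms.entries]
    cfg = SimConfig(
        rng_seed=7,
        n_controls=9,
        n_cases=6,
        arm_table=toy_arms,
        mean_read_pairs=2_000_000,
        events=[
            [CnvEvent(arm=names[i % len(names)], copy_state=3, tumor_fraction=0.4)]
            for i in range(6)
        ],
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
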