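import numpy as np
import pandas as pd
import pytest

from butolscreen import synthdata


@pytest.fixture(scope="session")
def small_genome():
    return synthdata.build_genome(100, 1000, 200_000, seed=1)


@pytest.fixture(scope="session")
def small_library(small_genome):
    return synthdata.simulate_library(small_genome, n_clones=600, insert_range=(2000, 3000), seed=2)


@pytest.fixture()
def schedule():
    return synthdata.StepSchedule()


def make_replicate_curves(
    gene: str,
    true_iie: float,
    seed: int,
    mu_wt_0: float = 0.6,
    t_wt: float = 0.5,
    noise_sd: float = 0.005,
    n_replicates: int = 4,
    butanol_pct: float = 0.5,
):
    """4-replicate clone + wild-type curve sets encoding a known IIE."""
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, 24.0 + 1e-9, 0.25)
    t_clone = t_wt * (1.0 + true_iie / 100.0)
    mu = {
        ("wt", 0.0): mu_wt_0,
        ("wt", butanol_pct): mu_wt_0 * t_wt,
        ("clone", 0.0): mu_wt_0,
        ("clone", butanol_pct): mu_wt_0 * t_clone,
    }
    curves = {"wt": [], "clone": []}
    for strain in ("wt", "clone"):
        for cond in (0.0, butanol_pct):
            for rep in range(1, n_replicates + 1):
                curves[strain].append(
                    synthdata.simulate_growth(
                        mu_max=mu[(strain, cond)], lag=2.0, carrying_capacity=1.3,
                        times=times, noise_sd=noise_sd, seed=int(rng.integers(2**31)),
                        od0=0.05, strain_id=gene if strain == "clone" else "WT",
                        condition=cond, replicate=rep,
                    )
                )
    return curves["clone"], curves["wt"]


@pytest.fixture()
def profile_frame():
    """Small gene x step profile matrix with two similar and one opposite gene."""
    return pd.DataFrame(
        {
            "s1": [1.0, 1.1, -1.0],
            "s2": [2.0, 2.1, -2.0],
            "s3": [3.0, 3.2, -3.0],
            "s4": [4.0, 4.1, -4.1],
        },
        index=["gA", "gB", "gC"],
    )
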