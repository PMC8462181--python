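"""Shared fixtures: toy trees, trait tables, and a small fitted posterior."""

import dendropy
import numpy as np
import pandas as pd
import pytest

import hiddendiv as hd


def make_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


@pytest.fixture()
def toy_tree():
    """4 tips: ((A:1,B:1):1,(C:2,D:2):0.5); total branch length 7.5."""
    return make_tree("((A:1,B:1):1,(C:2,D:2):0.5);")


@pytest.fixture()
def toy_traits():
    return hd.TraitMatrix(
        pd.DataFrame(
            {"size": [1.0, 2.0, 3.0, 5.0], "spots": [0, 1, 1, 0]},
            index=["A", "B", "C", "D"],
        ),
        binary=("spots",),
    )


@pytest.fixture()
def toy_comm():
    ab = np.array([[1, 2, 0, 0], [1, 1, 1, 1], [0, 0, 3, 1]])
    return hd.CommunityMatrix(ab, ("s1", "s2", "s3"), ("A", "B", "C", "D"))


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated metacommunity (6 species, 12 sites, 5 occasions)."""
    grid = hd.build_setting_grid(n_species=6, seed=11)
    return hd.simulate_metacommunity(grid[4])


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """A short 2-chain fit of the small simulation, shared across tests."""
    cfg = hd.MCMCConfig(n_chains=2, n_iter=800, n_burn=400, thin=4, seed=21)
    return hd.fit_model(small_sim.y, small_sim.design, cfg)


def batch_means_se(x: np.ndarray, n_batches: int = 25) -> float:
    """Monte Carlo standard error of a mean via batch means."""
    x = np.asarray(x, dtype=float)
    usable = (len(x) // n_batches) * n_batches
    batches = x[:usable].reshape(n_batches, -1).mean(axis=1)
    return float(batches.std(ddof=1) / np.sqrt(n_batches))
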