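import dendropy
import numpy as np
import pandas as pd
import pytest

import basinnet as bn
from basinnet.seeding import derive_seed

MASTER_SEED = 0


def make_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — the worked example topology."""
    return make_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def rng():
    return np.random.default_rng(MASTER_SEED)


def synthetic_dataset(
    seed: int,
    n_species: int = 300,
    n_basins: int = 225,
    range_radius: float = 0.28,
    lambda_signal: float = 1.0,
    competition_strength: float = 0.0,
    filtering_strength: float = 0.0,
    competition_quantile: float = 0.4,
):
    """One full synthetic dataset: occurrence, CD, PD, coordinates, traits.

    The competition threshold is set to the given quantile of the
    all-pairs cosine-distance distribution, the convention used by all
    planted-competition analyses here.
    """
    tree = bn.simulate_tree(n_species, 1.0, seed=derive_seed(seed, "tree"))
    traits = bn.simulate_traits(
        tree, 10, lambda_signal, 1.0, seed=derive_seed(seed, "traits")
    )
    pd_mat = bn.cophenetic_distances(tree)
    cd = bn.pairwise_cd(bn.normalize_traits(traits))
    tau = float(
        np.quantile(
            cd.to_numpy()[np.triu_indices(n_species, 1)], competition_quantile
        )
    )
    cfg = bn.GeneratorConfig(
        n_species=n_species,
        n_basins=n_basins,
        range_radius=range_radius,
        lambda_signal=lambda_signal,
        competition_strength=competition_strength,
        competition_threshold=tau,
        filtering_strength=filtering_strength,
        seed=derive_seed(seed, "occurrence"),
    )
    occ, coords = bn.simulate_occurrence(traits, pd_mat, cfg)
    return {
        "tree": tree,
        "traits": traits,
        "occ": occ,
        "cd": cd,
        "pd": pd_mat,
        "coords": coords,
        "tau": tau,
        "config": cfg,
    }


@pytest.fixture(scope="session")
def small_dataset():
    """A small neutral dataset shared by fast structural tests."""
    return synthetic_dataset(
        MASTER_SEED, n_species=40, n_basins=49, range_radius=0.18
    )


def random_occurrence(rng, n_species=12, n_basins=8, p=0.4) -> pd.DataFrame:
    occ = (rng.random((n_species, n_basins)) < p).astype(np.int8)
    return pd.DataFrame(
        occ,
        index=[f"s{i:03d}" for i in range(n_species)],
        columns=[f"b{j:03d}" for j in range(n_basins)],
    )
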