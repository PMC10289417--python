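"""Synthetic trees, traits and occurrence matrices with known structure.

Real analyses of this kind rest on three inputs that cannot be bundled:
a species-level phylogeny, a species x trait table and a species x basin
presence/absence table. This module generates all three with *tunable*
statistical structure so that every downstream stage has a
parameter-recovery test:

* :func:`simulate_tree` — a pure-birth (Yule) tree;
* :func:`simulate_traits` — traits evolved on the tree with phylogenetic
  signal controlled by a Pagel-lambda covariance transform;
* :func:`simulate_occurrence` — spatially clustered ranges on a basin grid,
  optionally thinned by a competition mechanism (morphologically similar
  co-occurring pairs are pruned) and/or an environmental-filtering
  mechanism (species survive best in basins matching their trait optimum).

With both mechanism strengths at zero the occurrence matrix is independent
of traits and phylogeny, giving the null condition for calibration tests.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import asdict, dataclass

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .errors import InvalidArgumentError, InvalidDataError
from .phylo import lambda_transform, phylo_covariance
from .traits import normalize_traits, pairwise_cd

__all__ = ["GeneratorConfig", "simulate_tree", "simulate_traits", "simulate_occurrence"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic-data generator.

    Defaults describe the package's canonical species-network scenario:
    300 species on a 15 x 15 basin grid with broadly overlapping circular
    ranges (radius 0.28 of the domain diameter), Brownian traits with full
    phylogenetic signal, and both assembly mechanisms switched off. At
    this scale the nearest-neighbour species networks decompose into
    module counts comparable to the continental-scale analyses the
    generator emulates (about ten modules at NN = 10).
    """

    n_species: int = 300
    n_traits: int = 10
    n_basins: int = 225
    birth_rate: float = 1.0
    lambda_signal: float = 1.0
    bm_rate: float = 1.0
    range_radius: float = 0.28
    competition_strength: float = 0.0
    competition_threshold: float = 0.05
    filtering_strength: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 3:
            raise InvalidArgumentError("n_species must be >= 3")
        if self.n_basins < 2:
            raise InvalidArgumentError("n_basins must be >= 2")
        if not 0.0 < self.range_radius <= 1.0:
            raise InvalidArgumentError("range_radius must be in (0, 1]")
        for name in ("lambda_signal", "competition_strength", "filtering_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidArgumentError(f"{name} must be in [0, 1], got {v}")
        if self.competition_threshold <= 0:
            raise InvalidArgumentError("competition_threshold must be > 0")
        if self.bm_rate <= 0 or self.birth_rate <= 0:
            raise InvalidArgumentError("rates must be > 0")


def species_label(i: int) -> str:
    return f"s{i + 1:04d}"


def basin_label(i: int) -> str:
    return f"b{i + 1:04d}"


def simulate_tree(n_species: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Simulate a pure-birth (Yule) tree with ``n_species`` tips.

    Tips are labelled ``s0001, s0002, ...``. The simulator stops when the
    target tip count is reached; pendant edges are then extended by the
    (memoryless) waiting time to the next speciation so the tree is sampled
    strictly inside the n-lineage epoch and all branch lengths are positive.
    Deterministic given ``seed``.
    """
    if n_species < 2:
        raise InvalidArgumentError("n_species must be >= 2")
    if birth_rate <= 0:
        raise InvalidArgumentError("birth_rate must be > 0")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=rng,
    )
    extra = rng.expovariate(n_species * birth_rate)
    leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    for i, leaf in enumerate(leaves):
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
        leaf.taxon.label = species_label(i)
    tree.seed_node.edge.length = None  # root edge carries no information here
    return tree


def simulate_traits(
    tree: dendropy.Tree,
    n_traits: int = 10,
    lambda_signal: float = 1.0,
    bm_rate: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Evolve ``n_traits`` independent traits on the tree.

    Each trait column is multivariate normal with covariance equal to the
    Pagel-lambda transform (strength ``lambda_signal``) of the tree's
    shared-path-length matrix, scaled by ``bm_rate``; lambda = 1 is plain
    Brownian motion, lambda = 0 removes all shared covariance. Columns are
    then shifted into the strictly positive orthant (add |min| + 1 per
    column) so cosine distances downstream stay in [0, 1].
    """
    if not 0.0 <= lambda_signal <= 1.0:
        raise InvalidArgumentError("lambda_signal must be in [0, 1]")
    if bm_rate <= 0:
        raise InvalidArgumentError("bm_rate must be > 0")
    if n_traits < 1:
        raise InvalidArgumentError("n_traits must be >= 1")
    v = phylo_covariance(tree)
    cov = bm_rate * lambda_transform(v, lambda_signal).to_numpy()
    n = cov.shape[0]
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, u = np.linalg.eigh(cov)
        chol = u * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    x = chol @ rng.standard_normal((n, n_traits))
    x += np.abs(x.min(axis=0)) + 1.0
    return pd.DataFrame(
        x, index=v.index, columns=[f"t{j + 1}" for j in range(n_traits)]
    )


def _basin_grid(n_basins: int) -> pd.DataFrame:
    """Basin centres on a regular grid filling the unit square."""
    side = math.isqrt(n_basins)
    if side * side < n_basins:
        side += 1
    coords = []
    for i in range(n_basins):
        r, c = divmod(i, side)
        coords.append((basin_label(i), (c + 0.5) / side, (r + 0.5) / side))
    return pd.DataFrame(coords, columns=["basin_id", "x", "y"]).set_index("basin_id")


def simulate_occurrence(
    traits: pd.DataFrame,
    pd_matrix: pd.DataFrame,
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a binary species x basin occurrence matrix plus coordinates.

    Baseline geometry: each species receives a uniform-random range centre
    in the unit square and is present in every basin whose grid centre lies
    within ``range_radius`` — overlapping circular ranges produce spatially
    clustered co-occurrence. Two thinning mechanisms then act per basin:

    * competition: for every co-present pair with cosine distance below
      ``competition_threshold`` (pairs visited in ascending index order),
      the larger-index member is removed with probability
      ``competition_strength``;
    * environmental filtering: each basin has environment ``e`` = its x
      coordinate and each species an optimum = its first normalized trait
      value; a present species is retained with probability
      ``1 - filtering_strength * |e - optimum|``.

    Thinning only ever removes presences. Species left with no basins are
    kept as all-zero rows (logged) and dropped only by downstream filters.
    Deterministic given ``config.seed``.
    """
    config.validate()
    if list(traits.index) != list(pd_matrix.index):
        if set(traits.index) != set(pd_matrix.index):
            raise InvalidDataError("traits and PD matrix cover different species")
        pd_matrix = pd_matrix.loc[traits.index, traits.index]
    species = list(traits.index)
    n_sp = len(species)
    coords = _basin_grid(config.n_basins)
    rng = np.random.default_rng(config.seed)

    centers = rng.uniform(0.0, 1.0, size=(n_sp, 2))
    bx = coords["x"].to_numpy()
    by = coords["y"].to_numpy()
    dist = np.hypot(centers[:, [0]] - bx[None, :], centers[:, [1]] - by[None, :])
    # radius is a fraction of the maximal centre-to-centre distance, so
    # range_radius = 1 makes every species cosmopolitan
    occ = (dist <= config.range_radius * math.sqrt(2.0)).astype(np.int8)

    norm = normalize_traits(traits)
    cd = pairwise_cd(norm).to_numpy()

    if config.competition_strength > 0:
        close_i, close_j = np.nonzero(
            np.triu(cd < config.competition_threshold, k=1)
        )
        for b in range(config.n_basins):
            present = occ[:, b].astype(bool)
            for i, j in zip(close_i, close_j):
                if present[i] and present[j]:
                    if rng.random() < config.competition_strength:
                        present[j] = False  # deterministic loser: larger index
            occ[:, b] = present

    if config.filtering_strength > 0:
        optimum = norm.iloc[:, 0].to_numpy()
        mismatch = np.abs(bx[None, :] - optimum[:, None])
        keep = rng.random(size=occ.shape) < 1.0 - config.filtering_strength * mismatch
        occ = occ * keep.astype(np.int8)

    empty = int((occ.sum(axis=1) == 0).sum())
    if empty:
        logger.info("%d species have no basin after thinning (kept as zero rows)", empty)
    occ_df = pd.DataFrame(occ, index=species, columns=coords.index)
    return occ_df, coords.reset_index()


def config_to_dict(config: GeneratorConfig) -> dict:
    return asdict(config)
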