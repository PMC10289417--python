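# basinnet

Network-based analysis of how fish **phylogeny**, **morphology** and
**co-occurrence** across river basins depend on one another.

Community ecology asks whether the species found together in a watershed are
there because they are ecologically similar (environmental filtering), because
similar species exclude each other (competition), or by chance. `basinnet`
implements a network framework for these questions on three standard inputs —
a species-level phylogeny (Newick), a species × trait table, and a binary
species × basin presence/absence table — and ships a fully tunable synthetic
generator so every statistical claim can be tested without proprietary data.

## The framework

**Distances.** Morphological distance between species is the cosine distance
of their normalized trait vectors in *n*-dimensional trait space,

&nbsp;&nbsp;&nbsp;&nbsp;CD(T₁, T₂) = 1 − cos θ = 1 − (T₁·T₂)/(‖T₁‖‖T₂‖),

which lies in [0, 1] for nonnegative traits and ignores vector magnitudes.
Phylogenetic distance PD(i, j) is the cophenetic (patristic) distance — the
branch length along the tree path between tips i and j.

**Networks.**
* *Basin network*: undirected, weighted; nodes are basins, the weight of an
  edge is the number of species two basins share. Louvain modularity
  optimization partitions basins into clusters, which inherit the geography of
  overlapping species ranges.
* *Species networks*: directed, unweighted; every species sends edges to its
  NN nearest neighbours under CD or PD. Leiden optimization of directed
  modularity partitions species into modules.

**Statistics.** Every basin (≥2 species) gets mean pairwise ⟨CD⟩ and ⟨PD⟩
over its residents; ⟨CD⟩ is regressed on ⟨PD⟩ within each basin cluster.
Every species module gets ⟨CD⟩, ⟨PD⟩ and **NBS** — the number of basins in
which at least two of its members co-occur. Two null hypotheses are tested by
OLS over modules: H₁ (NBS is unrelated to ⟨CD⟩) and H₂ (NBS is unrelated to
⟨PD⟩), swept over NN and compared against size-matched random-module nulls.
Phylogenetic signal of each trait is quantified by Blomberg's K (permutation
test) and Pagel's λ (profiled maximum likelihood, LR test).

## Worked example

Plant a competition signal (similar co-occurring species are thinned with
probability 0.8 below the 40th CD percentile) and recover it:

```python
import numpy as np
import basinnet as bn

tree   = bn.simulate_tree(300, birth_rate=1.0, seed=4)
traits = bn.simulate_traits(tree, n_traits=10, lambda_signal=1.0, bm_rate=1.0, seed=5)
pd_mat = bn.cophenetic_distances(tree)
cd     = bn.pairwise_cd(bn.normalize_traits(traits))

tau = float(np.quantile(cd.to_numpy()[np.triu_indices(300, 1)], 0.4))
cfg = bn.GeneratorConfig(competition_strength=0.8, competition_threshold=tau, seed=6)
occ, coords = bn.simulate_occurrence(traits, pd_mat, cfg)

part  = bn.detect_modules(bn.build_nn_graph(cd, 10), seed=7)
stats = bn.module_stats(part, occ, cd, pd_mat).dropna()
res   = bn.ols(stats["nbs"], stats["mean_cd"], "nbs", "mean_cd")
```

which prints

```
NN=10 trait network: 10 modules, Q = 0.717
NBS ~ <CD> over 10 modules: slope = 4744.0, R^2 = 0.44, p = 0.0369
trait t1: Blomberg K = 0.63, Pagel lambda = 1.00 (p = 2.6e-84)
```

Modules of mutually similar species co-occur in fewer basins — the planted
competition signal — and the Brownian traits carry the expected strong
phylogenetic signal. The same computation on a generator run with both
mechanisms switched off yields a non-significant regression.

The command-line surface wraps the same functions:

```bash
basinnet simulate  --config cfg.yaml --out data/ --seed 5
basinnet basin-net --occ data/occurrence.csv --traits data/traits.csv \
                   --tree data/tree.nwk --seed 7 --out basin/
basinnet sweep     --occ data/occurrence.csv --traits data/traits.csv \
                   --tree data/tree.nwk --metric cd --runs 100 --seed 7 --out sweep/
basinnet signal    --traits data/traits.csv --tree data/tree.nwk --seed 7 --out sig/
```

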