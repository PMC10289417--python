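# Methods

This note documents the models behind `basinnet`, the parameter choices that
matter, what the synthetic generator does and does not emulate, and the
numerical conventions.

## Distances

Traits are normalized per column by the maximum over the species set, so each
trait contributes on a comparable scale and the vectors stay in the
nonnegative orthant. Morphological distance is the cosine distance
CD = 1 − cos θ between trait vectors; for nonnegative vectors CD ∈ [0, 1] and
is invariant to overall scale. Missing trait values are a hard error —
imputation is an upstream concern and synthetic data is complete by
construction.

Phylogenetic distance is the cophenetic (patristic) distance. Internally it
is derived from the shared-path covariance matrix V (V[i,j] = root-to-MRCA
distance, V[i,i] = root-to-tip depth) through the identity
PD(i,j) = V[i,i] + V[j,j] − 2·V[i,j]; the test suite checks the same numbers
against dendropy's independent patristic-distance routine.

## Phylogenetic signal

**Blomberg's K** is the observed ratio MSE₀/MSE (mean squared error of the
trait about its phylogenetically weighted mean, over the GLS error under the
tree) divided by its Brownian-motion expectation
(tr V − n/(1ᵀV⁻¹1))/(n − 1). K ≈ 1 indicates Brownian-like signal; on a star
phylogeny K is identically 1. Significance comes from a tip-permutation test,
p = (1 + #{K_perm ≥ K_obs})/(n_perm + 1), default 999 permutations with a
mandatory seed.

**Pagel's λ** rescales the off-diagonal of V by λ ∈ [0, 1]. The estimate
maximizes the multivariate-normal likelihood with the mean and rate profiled
analytically at each λ (bounded scalar optimization, tolerance 1e-6, with the
endpoints λ = 0 and λ = 1 always evaluated so boundary solutions are exact).
The p-value is a likelihood-ratio test against λ = 0 on a χ²(1) reference —
ML rather than REML, matching the common default; the χ² reference is an
approximation when the estimate sits on the boundary.

V⁻¹ is applied through a symmetric Cholesky solve, never an explicit inverse.
If V is numerically singular (e.g. effectively zero-length branches) a ridge
of 1e-10·tr(V)/n is added once, with a warning.

## Networks and modules

Basin graphs are undirected with integer weights = shared-species counts;
basins sharing no species stay as isolated nodes and end up in singleton
modules, keeping partitions total. Species graphs are directed and unweighted:
each species points to its NN closest species under the chosen metric, with
ties broken by ascending species identifier so graph construction is exactly
reproducible. Modularity is the standard Newman quality for undirected
weighted graphs and the directed (out/in degree) variant for species graphs.
Louvain (networkx, seeded) optimizes the undirected case and Leiden
(leidenalg, seeded) the directed case, both at resolution 1; the package
recomputes Q for every returned partition with its own modularity function,
which the tests validate against exhaustive enumeration on small graphs.

## Module and basin statistics

⟨CD⟩ and ⟨PD⟩ are means over all unordered species pairs within a basin or
module; they are undefined below two species, and such units are excluded
from regressions. NBS counts the basins where at least `min_cooccur`
(default 2) module members are present — the weakest co-occurrence notion
that is not satisfied by a single species; the threshold is exposed as a
parameter for robustness checks. Regressions are ordinary least squares with
a two-sided t-test on the slope; a constant response returns slope 0, R² = 0,
p = 1 (nothing to explain) rather than an error, which matters when NBS
saturates at the total basin count.

NN sweeps rerun module detection `n_runs` times per NN with seeds derived
from the master seed (SHA-256 of "seed:stage:index", below 2³¹), and
aggregate per (NN, response): mean R², median p, median slope, and a
significance flag median-p < α (α = 0.05 throughout). Medians keep a single
degenerate run from dominating; the per-run table is always returned so other
aggregations can be audited. The random-module null redraws disjoint modules
of matched sizes from the species pool; the random-basin-cluster null
likewise samples basin pseudo-clusters of matched sizes without replacement.

## The synthetic generator

The generator emulates the three inputs of a continental-scale analysis:

* **Tree** — pure-birth (Yule) process conditioned on the tip count. The
  simulator stops at the n-th speciation, which leaves the newest sister pair
  at zero distance; all pendant edges are therefore extended by the
  exponential waiting time to the next speciation (memoryless, so the tree is
  a Yule tree observed within its n-lineage epoch) and every branch length is
  strictly positive.
* **Traits** — each of 10 columns is multivariate normal with covariance
  `bm_rate` × (Pagel-λ transform of V at strength `lambda_signal`), then
  shifted into the positive orthant (per column, add |min| + 1) so cosine
  distances stay in [0, 1]. λ = 1 is Brownian motion; λ = 0 removes all
  shared covariance.
* **Occurrence** — basins sit on a regular grid in the unit square; each
  species gets a uniform-random range centre and occupies every basin within
  `range_radius` (expressed as a fraction of the maximal centre-to-centre
  distance, so radius 1 makes a species cosmopolitan). Overlapping circular
  ranges give spatially clustered co-occurrence and geographically coherent
  basin modules. Two thinning mechanisms then act per basin, both seeded and
  monotone (they only remove presences):
  * *competition*: each co-present pair closer than `competition_threshold`
    in CD loses its larger-index member with probability
    `competition_strength` (pairs visited in ascending index order; a species
    already removed in that basin takes no further part);
  * *environmental filtering*: basin environment = x coordinate, species
    optimum = first normalized trait; retention probability
    1 − `filtering_strength`·|e − optimum|.

  With both strengths zero the matrix is independent of traits and phylogeny,
  the null condition for calibration tests. Species left with no basins stay
  as all-zero rows (logged) so bookkeeping is explicit downstream.

### Study scales

Two canonical scenarios are used by the tests and the acceptance script; both
were fixed once, from a pilot power analysis, before the statistical tests
were frozen:

* **Species-network scenario** (GeneratorConfig defaults): 300 species,
  225 basins, range_radius 0.28 (broad, strongly overlapping ranges). At this
  scale the CD-based NN = 10 network decomposes into ≈ 10 modules with
  Q ≈ 0.7 — the same module-count regime as continental fish datasets — and
  module co-occurrence is near its ceiling under the null, which keeps the
  H₁/H₂ regressions close to their nominal level when occurrence is
  independent of traits.
* **Basin scenario**: 100 species, 225 basins, range_radius 0.14, giving
  ≈ 9 resident species per basin and four to six geographic basin clusters of
  ≈ 50 basins — a richness regime where basin means vary enough between
  basins for the ⟨CD⟩ ~ ⟨PD⟩ cluster regressions to be informative.

The NN sweep defaults to NN ∈ [10, 25]. The floor mirrors the practice of
restricting sweeps to NN values with good modular structure, and avoids a
regime this generator makes explicitly visible (see Limitations): with many
small modules, module size couples to both NBS and ⟨CD⟩ and the NBS
regression becomes anti-conservative even under the independence null.

## Known limitations

* **What the generator does not emulate.** Range centres are uniform and
  independent of the phylogeny, so there is no phylogeographic turnover (no
  tendency of clades to occupy regions), no richness gradient, and no
  hydrological structure. Passing tests therefore demonstrate the pipeline's
  statistical behaviour under a minimal assembly model, not fidelity to any
  particular fauna.
* **Module-size confounding.** NBS grows mechanically with module size, and
  modules of a CD-based NN graph tend to span more trait space when larger.
  Under the independence null this couples NBS to ⟨CD⟩ through size alone;
  the effect strengthens when partitions contain many small modules (low NN
  relative to the species count). The default sweep floor avoids that regime;
  users lowering it should interpret significance flags with care.
* **Spatial pseudo-replication in basin regressions.** Neighbouring basins
  share most of their species, so within-cluster basin means are far from
  independent across basins. Within-cluster ⟨CD⟩ ~ ⟨PD⟩ regressions can
  therefore reach significance for reasons unrelated to trait–phylogeny
  coupling (the test suite documents a case where trait shuffling leaves
  ≈ 20 % of cluster regressions significant), and conversely particular
  Brownian draws can locally invert the relation in individual clusters. At
  this desk scale the per-cluster regressions should be read as descriptive.
* **Boundary p-values.** The χ²(1) reference for the λ likelihood-ratio test
  is conservative at λ̂ = 0; permutation p-values never report below
  1/(n_perm + 1).
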