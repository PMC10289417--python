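"""Phylogenetic distances and phylogenetic-signal statistics.

Distances come in two closely related forms:

* the cophenetic (patristic) distance ``PD[i, j]``: total branch length on
  the tree path between tips *i* and *j*;
* the phylogenetic covariance ``V[i, j]``: shared branch length from the
  root down to the most recent common ancestor of *i* and *j* (with
  ``V[i, i]`` the root-to-tip distance), the trait covariance implied by
  Brownian motion on the tree.

The two satisfy ``PD[i, j] = V[i, i] + V[j, j] - 2 V[i, j]`` on every tree,
which the test suite uses as a cross-check since the two are computed by
independent routes (dendropy's patristic distances vs. a root-distance
traversal here).

Phylogenetic signal of a trait is quantified by Blomberg's K (a variance
ratio with expectation ~1 under Brownian motion, with a tip-permutation
test) and Pagel's lambda (maximum-likelihood scaling of the off-diagonal
phylogenetic covariance, with a likelihood-ratio test against lambda = 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .errors import InvalidArgumentError, InvalidDataError, NumericalError

__all__ = [
    "tip_labels",
    "cophenetic_distances",
    "phylo_covariance",
    "lambda_transform",
    "blomberg_k",
    "blomberg_k_pvalue",
    "pagel_lambda",
    "SignalResult",
    "signal_table",
]


def _validate_tree(tree: dendropy.Tree) -> None:
    tips = [leaf for leaf in tree.leaf_node_iter()]
    if len(tips) < 2:
        raise InvalidDataError("tree must have at least 2 tips")
    labels = [leaf.taxon.label for leaf in tips]
    if len(set(labels)) != len(labels):
        raise InvalidDataError("tip labels are not unique")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise InvalidDataError(f"negative branch length {edge.length}")


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in the canonical (sorted) order used by all matrices."""
    return sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())


def cophenetic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Pairwise patristic distances between tips, as a labelled matrix.

    Computed from the shared-path decomposition: the path between tips i
    and j is their two root paths minus twice the shared part, so
    ``PD[i, j] = V[i, i] + V[j, j] - 2 V[i, j]``.
    """
    v = phylo_covariance(tree)
    arr = v.to_numpy()
    depths = np.diag(arr)
    d = depths[:, None] + depths[None, :] - 2.0 * arr
    np.clip(d, 0.0, None, out=d)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=v.index, columns=v.columns)


def phylo_covariance(tree: dendropy.Tree) -> pd.DataFrame:
    """Shared-path-length (Brownian-motion) covariance matrix of the tips.

    ``V[i, j]`` is the root-to-MRCA distance of tips i and j; the diagonal
    holds root-to-tip distances. The root edge, if any, is not counted.
    """
    _validate_tree(tree)
    labels = tip_labels(tree)
    index = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    v = np.zeros((n, n))
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    root_offset = tree.seed_node.root_distance  # 0 unless a root edge exists
    below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            k = index[node.taxon.label]
            v[k, k] = node.root_distance - root_offset
            below[id(node)] = [k]
        else:
            depth = node.root_distance - root_offset
            child_sets = [below.pop(id(c)) for c in node.child_nodes()]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    for i in child_sets[a]:
                        for j in child_sets[b]:
                            v[i, j] = v[j, i] = depth
            merged: list[int] = []
            for s in child_sets:
                merged.extend(s)
            below[id(node)] = merged
    return pd.DataFrame(v, index=labels, columns=labels)


def lambda_transform(v: pd.DataFrame, lam: float) -> pd.DataFrame:
    """Pagel transform: multiply off-diagonal covariances by ``lam``."""
    if not 0.0 <= lam <= 1.0:
        raise InvalidArgumentError(f"lambda must be in [0, 1], got {lam}")
    arr = v.to_numpy(dtype=float).copy()
    diag = np.diag(arr).copy()
    arr *= lam
    np.fill_diagonal(arr, diag)
    return pd.DataFrame(arr, index=v.index, columns=v.columns)


def _as_matrix(v) -> np.ndarray:
    return v.to_numpy(dtype=float) if isinstance(v, pd.DataFrame) else np.asarray(v, float)


def _chol(v: np.ndarray):
    """Cholesky factor of V; on singularity retry with a small ridge."""
    try:
        return cho_factor(v, lower=True)
    except LinAlgError:
        ridge = 1e-10 * np.trace(v) / v.shape[0]
        warnings.warn(
            f"phylogenetic covariance singular; adding ridge {ridge:.3e}",
            RuntimeWarning,
            stacklevel=3,
        )
        try:
            return cho_factor(v + ridge * np.eye(v.shape[0]), lower=True)
        except LinAlgError as exc:  # pragma: no cover - pathological input
            cond = np.linalg.cond(v)
            raise NumericalError(
                f"covariance not positive definite (condition number {cond:.3e})"
            ) from exc


def _k_batch(x: np.ndarray, v: np.ndarray, factor) -> np.ndarray:
    """Blomberg's K for each column of ``x`` (n x B), sharing one factor."""
    n = v.shape[0]
    ones = np.ones(n)
    vi1 = cho_solve(factor, ones)
    s = ones @ vi1
    ahat = (vi1 @ x) / s
    r = x - ahat
    mse0 = np.einsum("ib,ib->b", r, r) / (n - 1)
    mse = np.einsum("ib,ib->b", r, cho_solve(factor, r)) / (n - 1)
    expected = (np.trace(v) - n / s) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_k(x, v) -> float:
    """Blomberg's K of trait vector ``x`` given phylogenetic covariance ``v``.

    K compares the observed ratio of the trait's mean squared error around
    the phylogenetically corrected mean to the phylogenetically weighted
    mean squared error, against the value expected under Brownian motion;
    K ~ 1 indicates Brownian-like signal, K << 1 little signal.
    """
    vm = _as_matrix(v)
    xv = np.asarray(x, dtype=float).ravel()
    n = vm.shape[0]
    if n < 3:
        raise InvalidArgumentError("Blomberg's K needs at least 3 tips")
    if xv.shape[0] != n:
        raise InvalidDataError("trait vector length does not match covariance")
    if np.ptp(xv) == 0.0:
        raise InvalidDataError("constant trait vector: K undefined")
    factor = _chol(vm)
    return float(_k_batch(xv[:, None], vm, factor)[0])


def blomberg_k_pvalue(x, v, n_perm: int = 999, seed: int = 0) -> float:
    """Permutation p-value for Blomberg's K.

    Trait values are shuffled across tips ``n_perm`` times;
    p = (1 + #{K_perm >= K_obs}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise InvalidArgumentError("n_perm must be at least 99")
    vm = _as_matrix(v)
    xv = np.asarray(x, dtype=float).ravel()
    k_obs = blomberg_k(xv, vm)
    factor = _chol(vm)
    rng = np.random.default_rng(seed)
    perms = np.column_stack([rng.permutation(xv) for _ in range(n_perm)])
    k_perm = _k_batch(perms, vm, factor)
    return float((1 + np.sum(k_perm >= k_obs)) / (n_perm + 1))


def _lambda_loglik(lam: float, x: np.ndarray, v: np.ndarray) -> float:
    # profiled ML: mean and rate are solved analytically at each lambda
    n = v.shape[0]
    vl = v * lam
    np.fill_diagonal(vl, np.diag(v))
    factor = _chol(vl)
    logdet = 2.0 * np.sum(np.log(np.diag(factor[0])))
    ones = np.ones(n)
    vi1 = cho_solve(factor, ones)
    ahat = (vi1 @ x) / (ones @ vi1)
    r = x - ahat
    sigma2 = (r @ cho_solve(factor, r)) / n
    if sigma2 <= 0:
        return -np.inf
    return float(-0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n))


def pagel_lambda(x, v) -> tuple[float, float, float]:
    """Maximum-likelihood Pagel's lambda in [0, 1] with an LR test vs 0.

    Returns ``(lambda_hat, loglik, p_value)``. The likelihood is the
    multivariate normal of the trait with covariance sigma^2 *
    ``lambda_transform(v, lambda)``, mean and sigma^2 profiled analytically;
    the p-value is from a chi-squared(1) reference for 2 * (LL(lambda_hat) -
    LL(0)), an approximation at the boundary.
    """
    vm = _as_matrix(v)
    xv = np.asarray(x, dtype=float).ravel()
    if vm.shape[0] < 3:
        raise InvalidArgumentError("Pagel's lambda needs at least 3 tips")
    if np.ptp(xv) == 0.0:
        raise InvalidDataError("constant trait vector: lambda undefined")

    def neg(lam: float) -> float:
        return -_lambda_loglik(lam, xv, vm)

    res = minimize_scalar(neg, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-6})
    candidates = [(0.0, _lambda_loglik(0.0, xv, vm)),
                  (1.0, _lambda_loglik(1.0, xv, vm)),
                  (float(res.x), -float(res.fun))]
    lam_hat, ll_hat = max(candidates, key=lambda c: c[1])
    ll0 = candidates[0][1]
    lr = max(2.0 * (ll_hat - ll0), 0.0)
    p = float(chi2.sf(lr, df=1))
    return lam_hat, ll_hat, min(max(p, np.finfo(float).tiny), 1.0)


@dataclass(frozen=True)
class SignalResult:
    """Per-trait phylogenetic-signal summary."""

    trait: str
    k: float
    k_pvalue: float
    lam: float
    lam_loglik: float
    lam_pvalue: float


def signal_table(traits: pd.DataFrame, v: pd.DataFrame, n_perm: int = 999,
                 seed: int = 0) -> pd.DataFrame:
    """Blomberg's K and Pagel's lambda, with p-values, for every trait.

    ``traits`` rows must be aligned to the species order of ``v``.
    """
    missing = set(v.index) - set(traits.index)
    if missing:
        raise InvalidDataError(f"traits missing for species {sorted(missing)[:5]}")
    aligned = traits.loc[v.index]
    rows = []
    for i, name in enumerate(aligned.columns):
        x = aligned[name].to_numpy(dtype=float)
        k = blomberg_k(x, v)
        kp = blomberg_k_pvalue(x, v, n_perm=n_perm, seed=seed + i)
        lam, ll, lp = pagel_lambda(x, v)
        rows.append(SignalResult(name, k, kp, lam, ll, lp))
    return pd.DataFrame(
        {
            "trait": [r.trait for r in rows],
            "K": [r.k for r in rows],
            "K_pvalue": [r.k_pvalue for r in rows],
            "lambda": [r.lam for r in rows],
            "lambda_loglik": [r.lam_loglik for r in rows],
            "lambda_pvalue": [r.lam_pvalue for r in rows],
        }
    )
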