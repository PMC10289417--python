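"""Trait normalization and cosine distance in morphological trait space.

Species are represented as vectors in an ``n_traits``-dimensional trait
space. Morphological similarity between two species is the cosine of the
angle between their trait vectors (cosine similarity, CS); the morphological
distance used throughout the package is the cosine distance CD = 1 - CS.
For nonnegative trait vectors CD lies in [0, 1], and unlike Euclidean
distance it is invariant to the overall magnitude of the vectors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import InvalidDataError

__all__ = ["normalize_traits", "cosine_distance", "pairwise_cd"]


def normalize_traits(raw: pd.DataFrame) -> pd.DataFrame:
    """Normalize each trait column by its maximum over the species set.

    Parameters
    ----------
    raw : DataFrame
        Species x traits table, indexed by species identifier. Must be
        complete (no missing values); imputation is an upstream concern.

    Returns
    -------
    DataFrame
        Same shape; every column maximum equals 1.
    """
    if raw.isna().any().any():
        bad = raw.columns[raw.isna().any()].tolist()
        raise InvalidDataError(f"missing trait values in columns {bad}")
    maxima = raw.max(axis=0)
    nonpos = maxima[maxima <= 0]
    if len(nonpos) > 0:
        raise InvalidDataError(
            f"trait columns with non-positive maximum: {nonpos.index.tolist()}"
        )
    return raw / maxima


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine distance 1 - (u.v)/(|u||v|) between two trait vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise InvalidDataError("trait vectors have different lengths")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise InvalidDataError("zero-norm trait vector: angle undefined")
    return float(1.0 - (u @ v) / (nu * nv))


def pairwise_cd(traits: pd.DataFrame) -> pd.DataFrame:
    """All-pairs cosine-distance matrix over the species of ``traits``.

    The result is symmetric with an exactly zero diagonal; for nonnegative
    inputs every entry is in [0, 1].
    """
    x = traits.to_numpy(dtype=float)
    norms = np.linalg.norm(x, axis=1)
    if np.any(norms == 0.0):
        offenders = traits.index[norms == 0.0].tolist()
        raise InvalidDataError(f"zero-norm trait vectors for species {offenders}")
    d = squareform(pdist(x, metric="cosine"))
    np.clip(d, 0.0, None, out=d)  # guard tiny negative rounding
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=traits.index, columns=traits.index)
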