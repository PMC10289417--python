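"""Readers, writers and pipeline configuration.

All tabular interchange uses comma-separated UTF-8 CSV with a mandatory
header row and ``.`` decimals so round-trips are reproducible. Occurrence
data may arrive in long format (``species_id,basin_id`` rows) or as a wide
0/1 matrix with a ``species_id`` column; the reader auto-detects from the
header. Trees are Newick with branch lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .errors import InvalidArgumentError, InvalidDataError

__all__ = [
    "PipelineConfig",
    "read_occurrence",
    "write_occurrence",
    "read_traits",
    "write_traits",
    "read_tree",
    "write_tree",
    "read_pd_matrix",
    "write_matrix",
    "intersect_species",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat configuration for the command-line pipeline."""

    occurrence: str | None = None
    traits: str | None = None
    tree: str | None = None
    pd_matrix: str | None = None
    basin_coords: str | None = None
    metric: str = "cd"
    nn: int = 10
    nn_min: int = 10
    nn_max: int = 25
    nn_step: int = 1
    n_runs: int = 100
    n_permutations: int = 999
    seed: int | None = None
    alpha: float = 0.05
    out_dir: str = "."
    generator: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.seed is None:
            raise InvalidArgumentError("a seed is mandatory")
        if not 0.0 < self.alpha < 1.0:
            raise InvalidArgumentError("alpha must be in (0, 1)")
        if self.metric not in ("cd", "pd"):
            raise InvalidArgumentError("metric must be 'cd' or 'pd'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def read_occurrence(path: str | Path) -> pd.DataFrame:
    """Read an occurrence table, auto-detecting long vs wide format.

    Long format has exactly the columns ``species_id,basin_id``; anything
    else with a ``species_id`` column is treated as a wide 0/1 matrix.
    Duplicate long rows collapse to one presence. Species and basin order
    follow first appearance.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise InvalidDataError(f"empty occurrence file {path}")
    cols = list(df.columns)
    if cols[:2] == ["species_id", "basin_id"] and len(cols) == 2:
        species = list(dict.fromkeys(df["species_id"]))
        basins = list(dict.fromkeys(df["basin_id"]))
        occ = pd.DataFrame(0, index=species, columns=basins, dtype=np.int8)
        for sp, b in zip(df["species_id"], df["basin_id"]):
            occ.at[sp, b] = 1
        return occ
    if cols[0] != "species_id":
        raise InvalidDataError("occurrence file must start with a species_id column")
    wide = df.set_index("species_id")
    arr = wide.to_numpy()
    bad = ~np.isin(arr, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise InvalidDataError(
            f"non-binary cell {arr[i, j]!r} at species {wide.index[i]!r}, "
            f"basin {wide.columns[j]!r}"
        )
    return wide.astype(np.int8)


def write_occurrence(occ: pd.DataFrame, path: str | Path) -> None:
    """Write an occurrence matrix in long format (one row per presence)."""
    species, basins = np.nonzero(occ.to_numpy())
    pd.DataFrame(
        {
            "species_id": [occ.index[i] for i in species],
            "basin_id": [occ.columns[j] for j in basins],
        }
    ).to_csv(path, index=False)


def read_traits(path: str | Path) -> pd.DataFrame:
    """Read a species x trait table; missing or non-numeric cells are fatal."""
    df = pd.read_csv(path)
    if "species_id" not in df.columns:
        raise InvalidDataError("traits file needs a species_id column")
    traits = df.set_index("species_id")
    if traits.shape[1] < 1:
        raise InvalidDataError("traits file has no trait columns")
    for col in traits.columns:
        numeric = pd.to_numeric(traits[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            sp = traits.index[bad][0]
            raise InvalidDataError(
                f"missing or non-numeric value for species {sp!r}, trait {col!r}"
            )
        traits[col] = numeric
    return traits


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    traits.rename_axis("species_id").to_csv(path)


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree with branch lengths."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise InvalidDataError(f"cannot parse Newick file {path}: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise InvalidDataError(f"negative branch length in {path}")
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_pd_matrix(path: str | Path) -> pd.DataFrame:
    """Read a square labelled distance matrix; must be symmetric."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise InvalidDataError("distance matrix row and column labels differ")
    arr = df.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=1e-9):
        raise InvalidDataError("distance matrix is asymmetric beyond 1e-9")
    arr = (arr + arr.T) / 2.0
    np.fill_diagonal(arr, 0.0)
    return pd.DataFrame(arr, index=df.index, columns=df.columns)


def write_matrix(mat: pd.DataFrame, path: str | Path) -> None:
    mat.to_csv(path)


def intersect_species(
    occ: pd.DataFrame,
    traits: pd.DataFrame,
    pd_matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Restrict all inputs to the species present in every one of them.

    Mirrors the prune-to-shared-species step of real analyses; dropped
    species are counted per source and logged, never an error, as long as
    at least three species survive.
    """
    keep = [s for s in occ.index if s in set(traits.index) & set(pd_matrix.index)]
    report = {
        "n_shared": len(keep),
        "dropped_from_occurrence": int(len(occ.index) - len(keep)),
        "dropped_from_traits": int(len(traits.index) - len(keep)),
        "dropped_from_pd": int(len(pd_matrix.index) - len(keep)),
    }
    if len(keep) < 3:
        raise InvalidDataError(
            f"only {len(keep)} species shared between occurrence, traits and tree"
        )
    if any(v for k, v in report.items() if k.startswith("dropped")):
        logger.warning("species intersection: %s", report)
    return (
        occ.loc[keep],
        traits.loc[keep],
        pd_matrix.loc[keep, keep],
        report,
    )


def save_yaml(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
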