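"""The PPI stage: a TF-TF interaction prior from a STRING-style table.

The TFs that entered the motif prior are looked up in an interaction table
(STRING export dialect: protein1, protein2, combined_score on a 0-1000
scale).  Interactions are kept only when both endpoints are prior TFs;
combined scores are rescaled to [0, 1] by /1000 (the convention downstream
network-inference tools expect), symmetric duplicate rows collapse to the
maximum score, and self-interactions default to weight 1.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

logger = logging.getLogger(__name__)

PPI_COLUMNS = ["tf_a", "tf_b", "weight"]
WEIGHT_FORMAT = "%.3f"


@dataclass
class PPIEdges:
    """Undirected TF-TF edges with confidence weights in [0, 1].

    Endpoints are stored canonically (tf_a <= tf_b) so the edge set is
    invariant under swapping the input's endpoint columns.
    """

    edges: pd.DataFrame

    def __post_init__(self) -> None:
        self.edges = canonical_ppi_sort(self.edges)

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def node_names(self) -> set[str]:
        return set(self.edges["tf_a"]) | set(self.edges["tf_b"])

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["tf_a"], self.edges["tf_b"]))


def canonical_ppi_sort(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        return pd.DataFrame(columns=PPI_COLUMNS)
    return df.sort_values(["tf_a", "tf_b"], kind="mergesort").reset_index(drop=True)


def build_ppi(
    tf_names: Iterable[str],
    interactions: pd.DataFrame,
    include_self: bool = True,
    rescale: bool = True,
) -> PPIEdges:
    """Restrict an interaction table to the given TFs.

    ``interactions`` needs columns protein1, protein2, combined_score.
    Matching is by uppercase symbol.  Rows with an endpoint outside
    ``tf_names`` are dropped silently; an empty TF set is an error.
    """
    tfs = {str(t).upper() for t in tf_names}
    if not tfs:
        raise ValueError("cannot build a PPI prior for an empty TF set")
    for col in ("protein1", "protein2", "combined_score"):
        if col not in interactions.columns:
            raise ValueError(f"missing column {col} in interaction table")

    best: dict[tuple[str, str], float] = {}
    for row in interactions.itertuples(index=False):
        a, b = str(row.protein1).upper(), str(row.protein2).upper()
        if a not in tfs or b not in tfs or a == b:
            continue
        score = float(row.combined_score)
        weight = score / 1000.0 if rescale else score
        key = (a, b) if a <= b else (b, a)
        if weight > best.get(key, -1.0):
            best[key] = weight

    if include_self:
        for t in tfs:
            best[(t, t)] = 1.0

    edges = pd.DataFrame(
        [(a, b, w) for (a, b), w in best.items()], columns=PPI_COLUMNS
    )
    return PPIEdges(edges)


def write_ppi_prior(ppi: PPIEdges, path: Union[str, Path]) -> None:
    """Write the PPI prior: headerless TSV (tf_a, tf_b, weight), 3-decimal weights."""
    if ppi.edges.empty:
        logger.warning("writing empty PPI prior to %s", path)
    ppi.edges.to_csv(
        path, sep="\t", header=False, index=False, float_format=WEIGHT_FORMAT
    )


def read_ppi_prior(path: Union[str, Path]) -> PPIEdges:
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=PPI_COLUMNS, dtype={0: str, 1: str}
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=PPI_COLUMNS)
    if not df.empty:
        df["weight"] = df["weight"].astype(float)
    return PPIEdges(df)


def load_interactions(path: Union[str, Path]) -> pd.DataFrame:
    """Read a STRING-dialect interaction table (protein1, protein2, combined_score)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("protein1", "protein2", "combined_score"):
        if col not in df.columns:
            raise ValueError(f"missing column {col} in interaction table {path}")
    return df
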