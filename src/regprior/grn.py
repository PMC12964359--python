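"""Postprocessing of the motif stage into the motif prior.

Transcript-level matches are aggregated into genes (an edge TF -> gene exists
iff any transcript of the gene retained a match for that TF), gene IDs can
optionally be converted to gene names, and the prior is written as a sparse
PANDA-compatible edge list: headerless three-column TSV (tf, gene, weight)
with binary weights, deterministically sorted so priors are diffable.

When several gene IDs map to the same name, only the ID with the highest
number of TF binding sites — measured as distinct TF partners after best-hit
collapsing — keeps its edges; ties break by lexicographically smaller ID.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Union

import pandas as pd

logger = logging.getLogger(__name__)

GENE_ID = "gene_id"
GENE_NAME = "gene_name"

EDGE_COLUMNS = ["tf", "gene", "weight"]


@dataclass
class MotifPriorEdges:
    """Sparse TF -> gene edge set with binary weights.

    ``edges`` has columns tf, gene, weight (weight is always 1 for present
    edges; absent edges are implicit zeros).  ``gene_key_kind`` records
    whether genes are keyed by ID or by name.
    """

    edges: pd.DataFrame
    gene_key_kind: str = GENE_ID

    def __post_init__(self) -> None:
        self.edges = canonical_edge_sort(self.edges)

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def tf_names(self) -> set[str]:
        return set(self.edges["tf"])

    @property
    def gene_keys(self) -> set[str]:
        return set(self.edges["gene"])

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["tf"], self.edges["gene"]))


def canonical_edge_sort(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    return df.sort_values(["tf", "gene"], kind="mergesort").reset_index(drop=True)


def aggregate_to_genes(matches: pd.DataFrame) -> MotifPriorEdges:
    """Collapse transcript matches into gene-level binary edges."""
    if matches.empty:
        return MotifPriorEdges(pd.DataFrame(columns=EDGE_COLUMNS), GENE_ID)
    pairs = matches[["tf_name", "gene_id"]].drop_duplicates()
    edges = pd.DataFrame(
        {"tf": pairs["tf_name"], "gene": pairs["gene_id"], "weight": 1}
    )
    return MotifPriorEdges(edges, GENE_ID)


def convert_ids_to_names(
    prior: MotifPriorEdges, id_to_name: Mapping[str, str]
) -> MotifPriorEdges:
    """Re-key gene IDs to gene names with deterministic collision resolution.

    Among IDs sharing a name, the one with the most distinct TF partners in
    the prior wins; ties go to the lexicographically smaller ID (logged).
    IDs absent from the map keep the ID itself as key, with a log notice.
    """
    if prior.gene_key_kind != GENE_ID:
        raise ValueError("prior is already keyed by gene name")
    if prior.edges.empty:
        return MotifPriorEdges(prior.edges.copy(), GENE_NAME)

    partners = prior.edges.groupby("gene")["tf"].nunique()

    # choose a winning ID per target name
    target: dict[str, str] = {}
    winner: dict[str, str] = {}
    unmapped: list[str] = []
    for gid in sorted(partners.index):
        name = id_to_name.get(gid)
        if name is None:
            unmapped.append(gid)
            name = gid
        target[gid] = name
        cur = winner.get(name)
        if cur is None:
            winner[name] = gid
        else:
            n_cur, n_new = partners[cur], partners[gid]
            if n_new > n_cur:
                winner[name] = gid
            elif n_new == n_cur:
                logger.info(
                    "gene name %s: tie between %s and %s (%d TF partners); "
                    "keeping %s",
                    name,
                    cur,
                    gid,
                    n_cur,
                    min(cur, gid),
                )
                winner[name] = min(cur, gid)
    if unmapped:
        logger.warning(
            "%d gene ID(s) missing from the name map keep their ID as key",
            len(unmapped),
        )

    keep = {gid for name, gid in winner.items()}
    edges = prior.edges[prior.edges["gene"].isin(keep)].copy()
    edges["gene"] = edges["gene"].map(target)
    return MotifPriorEdges(edges, GENE_NAME)


def write_motif_prior(prior: MotifPriorEdges, path: Union[str, Path]) -> None:
    """Write the PANDA-compatible edge list: headerless TSV (tf, gene, weight)."""
    if prior.edges.empty:
        logger.warning("writing empty motif prior to %s", path)
    prior.edges.to_csv(path, sep="\t", header=False, index=False)


def read_motif_prior(
    path: Union[str, Path], gene_key_kind: str = GENE_ID
) -> MotifPriorEdges:
    """Read a motif prior written by :func:`write_motif_prior`."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=EDGE_COLUMNS, dtype={0: str, 1: str}
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=EDGE_COLUMNS)
    if not df.empty:
        df["weight"] = df["weight"].astype(int)
    return MotifPriorEdges(df, gene_key_kind)


def load_id_name_map(path: Union[str, Path]) -> dict[str, str]:
    """Read a gene ID -> name map TSV with columns gene_id, gene_name."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (GENE_ID, GENE_NAME):
        if col not in df.columns:
            raise ValueError(f"missing column {col} in gene name map {path}")
    return dict(zip(df[GENE_ID], df[GENE_NAME]))
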