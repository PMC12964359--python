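"""The motif stage: intersect binding-site tracks with regions of interest.

Binding sites come from precomputed genome-wide motif-scan tracks in a BED5
dialect (chrom, start, end, name=TF, score), either as one genome-wide file
or as one file per TF.  For every (region of interest, TF) combination only
the single best-scoring overlapping site is retained, and matches below a
minimum score threshold (400 by default, on the JASPAR track score scale)
are discarded.  Processing is sharded by scaffold; the result is invariant
to the sharding, the worker count and the track layout.
"""

from __future__ import annotations

import glob
import logging
import os
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import pandas as pd
from intervaltree import IntervalTree

from .regions import Region, RegionSet

logger = logging.getLogger(__name__)

#: Default minimum score for a match to enter the prior.
DEFAULT_SCORE_THRESHOLD = 400

MATCH_COLUMNS = ["tf_name", "transcript_id", "gene_id", "gene_name", "best_score"]

WHOLE_GENOME = "whole-genome"
PER_TF = "per-TF"


@dataclass(frozen=True)
class BindingSite:
    """One scored TF match on the genome (0-based half-open interval)."""

    scaffold: str
    start: int
    end: int
    tf_name: str
    score: int


@dataclass
class ReadStats:
    """Counters for rows skipped while reading a track."""

    skipped: int = 0
    reasons: dict[str, int] = field(default_factory=dict)

    def count(self, reason: str) -> None:
        self.skipped += 1
        self.reasons[reason] = self.reasons.get(reason, 0) + 1


def read_sites(
    path: Union[str, Path],
    tf_filter: Optional[set[str]] = None,
    stats: Optional[ReadStats] = None,
    scaffolds: Optional[set[str]] = None,
) -> Iterator[BindingSite]:
    """Stream binding sites from a BED-dialect TSV track.

    Malformed rows (too few fields, unparseable coordinates or score,
    ``end <= start``) are skipped and counted, never fatal.  ``tf_filter``
    restricts the stream to the catalog's TFs; ``scaffolds`` restricts to a
    shard.  Sites are yielded in file order (tracks are conventionally
    grouped by scaffold).
    """
    own_stats = stats if stats is not None else ReadStats()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                own_stats.count("too_few_fields")
                continue
            chrom, start_s, end_s, name, score_s = fields[:5]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                own_stats.count("bad_coordinates")
                continue
            try:
                score = int(score_s)
            except ValueError:
                own_stats.count("bad_score")
                continue
            if end <= start or start < 0 or score < 0:
                own_stats.count("invalid_interval_or_score")
                continue
            if tf_filter is not None and name not in tf_filter:
                continue
            if scaffolds is not None and chrom not in scaffolds:
                continue
            yield BindingSite(chrom, start, end, name, score)
    if own_stats.skipped and stats is None:
        logger.warning("skipped %d malformed row(s) in %s", own_stats.skipped, path)


def _better(
    cand: tuple[int, int, int], incumbent: tuple[int, int, int]
) -> bool:
    """Best-hit order: higher score, then smaller start, then smaller end."""
    c_score, c_start, c_end = cand
    i_score, i_start, i_end = incumbent
    return (-c_score, c_start, c_end) < (-i_score, i_start, i_end)


def best_hit_per_region_tf(
    regions: RegionSet,
    sites: Iterable[BindingSite],
    score_threshold: int = DEFAULT_SCORE_THRESHOLD,
) -> pd.DataFrame:
    """Keep the single best-scoring site per (region, TF) combination.

    A site matches a region iff the half-open intervals share at least one
    base.  Matches scoring below ``score_threshold`` are absent from the
    output.  Score ties break deterministically by smaller start, then
    smaller end, so the result is independent of site order and track layout.

    Returns the match table: one row per (tf_name, transcript_id) with the
    gene linkage and the best score, canonically sorted.
    """
    trees: dict[str, IntervalTree] = {}
    region_list: list[Region] = list(regions)
    for idx, r in enumerate(region_list):
        trees.setdefault(r.scaffold, IntervalTree()).addi(r.start, r.end, idx)

    # (region index, tf) -> (score, start, end)
    best: dict[tuple[int, str], tuple[int, int, int]] = {}
    for s in sites:
        if s.score < score_threshold:
            continue
        tree = trees.get(s.scaffold)
        if tree is None:
            continue
        cand = (s.score, s.start, s.end)
        for iv in tree.overlap(s.start, s.end):
            key = (iv.data, s.tf_name)
            cur = best.get(key)
            if cur is None or _better(cand, cur):
                best[key] = cand

    rows = []
    for (ridx, tf), (score, _, _) in best.items():
        r = region_list[ridx]
        rows.append((tf, r.transcript_id, r.gene_id, r.gene_name, score))
    df = pd.DataFrame(rows, columns=MATCH_COLUMNS)
    df["best_score"] = df["best_score"].astype("int64")
    return canonical_match_sort(df)


def canonical_match_sort(df: pd.DataFrame) -> pd.DataFrame:
    """Sort a match table by (tf_name, transcript_id) for byte-stable equality."""
    return df.sort_values(["tf_name", "transcript_id"], kind="mergesort").reset_index(
        drop=True
    )


def per_tf_tracks(directory: Union[str, Path]) -> dict[str, str]:
    """Map TF name -> track path for a per-TF layout directory.

    Files are named ``<TF>.bed`` or ``<TF>.tsv``; the stem is the TF name.
    """
    paths = sorted(
        glob.glob(os.path.join(str(directory), "*.bed"))
        + glob.glob(os.path.join(str(directory), "*.tsv"))
    )
    return {Path(p).stem: p for p in paths}


def _normalize_tracks(
    tracks: Union[str, Path, Mapping[str, Union[str, Path]]],
    layout: str,
) -> list[tuple[Optional[str], str]]:
    """Return a list of (tf restriction or None, path) to read."""
    if layout == WHOLE_GENOME:
        if isinstance(tracks, Mapping):
            raise ValueError("whole-genome layout takes a single track path")
        return [(None, str(tracks))]
    if layout == PER_TF:
        if not isinstance(tracks, Mapping):
            mapping = per_tf_tracks(tracks)
        else:
            mapping = {tf: str(p) for tf, p in tracks.items()}
        return [(tf, mapping[tf]) for tf in sorted(mapping)]
    raise ValueError(f"unknown track layout {layout!r}")


def _process_shard(
    region_rows: list[tuple],
    track_jobs: list[tuple[Optional[str], str]],
    scaffolds: set[str],
    score_threshold: int,
    tf_filter: Optional[set[str]],
) -> pd.DataFrame:
    regions = RegionSet([Region(*row) for row in region_rows])

    def site_stream() -> Iterator[BindingSite]:
        for tf, path in track_jobs:
            if tf is None:
                restrict = tf_filter
            else:
                restrict = {tf} if tf_filter is None else {tf} & tf_filter
                if not restrict:
                    continue
            yield from read_sites(path, tf_filter=restrict, scaffolds=scaffolds)

    return best_hit_per_region_tf(regions, site_stream(), score_threshold)


def process_sharded(
    regions: RegionSet,
    tracks: Union[str, Path, Mapping[str, Union[str, Path]]],
    layout: str = WHOLE_GENOME,
    score_threshold: int = DEFAULT_SCORE_THRESHOLD,
    workers: int = 1,
    shards: Optional[Sequence[set[str]]] = None,
    tf_filter: Optional[set[str]] = None,
) -> pd.DataFrame:
    """Run the motif stage shard-by-shard, optionally in parallel.

    ``shards`` partitions the region scaffold set (default: one shard per
    scaffold).  The output equals :func:`best_hit_per_region_tf` on the
    unsharded input and is independent of shard order and worker count.
    Scaffolds present in the track but absent from the regions contribute
    nothing.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    region_scaffolds = regions.scaffolds()
    if shards is None:
        shard_list = [{s} for s in sorted(region_scaffolds)]
    else:
        shard_list = [set(s) & region_scaffolds for s in shards]
        covered = set().union(*shard_list) if shard_list else set()
        if covered != region_scaffolds:
            missing = region_scaffolds - covered
            raise ValueError(f"shards do not cover scaffolds: {sorted(missing)}")

    track_jobs = _normalize_tracks(tracks, layout)
    jobs = []
    for shard in shard_list:
        if not shard:
            continue
        sub = regions.subset(shard)
        rows = [
            (r.scaffold, r.start, r.end, r.transcript_id, r.gene_id, r.gene_name)
            for r in sub
        ]
        jobs.append((rows, track_jobs, shard, score_threshold, tf_filter))

    if workers == 1 or len(jobs) <= 1:
        parts = [_process_shard(*job) for job in jobs]
    else:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            parts = list(pool.map(_process_shard, *zip(*jobs)))

    parts = [p for p in parts if not p.empty]
    if not parts:
        empty = pd.DataFrame(columns=MATCH_COLUMNS)
        empty["best_score"] = empty["best_score"].astype("int64")
        return empty
    return canonical_match_sort(pd.concat(parts, ignore_index=True))


def write_match_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Export the match table as a TSV with header."""
    df.to_csv(path, sep="\t", index=False)


def read_match_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"best_score": int})
    return canonical_match_sort(df)
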