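"""Regions of interest: promoter windows around transcription start sites.

The default region of interest for a transcript spans from a fixed number of
bases upstream of its transcription start site (TSS) to a fixed number of
bases downstream, on the transcript's own strand.  Users may instead supply a
ready-made region file (e.g. enhancer calls), in which case the windows are
used verbatim.

All coordinates are 0-based, half-open (BED convention), matching the
binding-site tracks the regions are intersected with.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

logger = logging.getLogger(__name__)

#: Default promoter window, in bases relative to the TSS.
DEFAULT_UPSTREAM = 750
DEFAULT_DOWNSTREAM = 250

REGION_COLUMNS = ["scaffold", "start", "end", "transcript_id", "gene_id"]
OPTIONAL_REGION_COLUMNS = ["gene_name", "strand"]

#: Sentinel for RegionSet.window_params when regions came from a user file.
USER_PROVIDED = "user-provided"


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript of the annotation: TSS position plus gene linkage."""

    scaffold: str
    tss: int
    strand: str
    transcript_id: str
    gene_id: str
    gene_name: Optional[str] = None


@dataclass(frozen=True)
class Region:
    """A genomic interval of interest linked to a transcript and its gene.

    ``start`` is inclusive, ``end`` exclusive; ``0 <= start < end``.
    """

    scaffold: str
    start: int
    end: int
    transcript_id: str
    gene_id: str
    gene_name: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for "
                f"transcript {self.transcript_id}"
            )


@dataclass
class RegionSet:
    """Collection of regions plus the window parameters that produced them.

    ``window_params`` is either an ``(upstream, downstream)`` tuple or the
    string ``"user-provided"`` for regions loaded from a file.
    """

    regions: list[Region] = field(default_factory=list)
    window_params: Union[tuple[int, int], str] = USER_PROVIDED

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def scaffolds(self) -> set[str]:
        return {r.scaffold for r in self.regions}

    def by_scaffold(self) -> dict[str, list[Region]]:
        out: dict[str, list[Region]] = {}
        for r in self.regions:
            out.setdefault(r.scaffold, []).append(r)
        return out

    def subset(self, scaffolds: Iterable[str]) -> "RegionSet":
        """Regions restricted to the given scaffolds, order preserved."""
        wanted = set(scaffolds)
        return RegionSet(
            [r for r in self.regions if r.scaffold in wanted], self.window_params
        )


def build_promoter_regions(
    transcripts: Iterable[TranscriptRecord],
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> RegionSet:
    """Build one promoter window per transcript.

    On the + strand the window is ``[tss - upstream, tss + downstream)``; on
    the - strand upstream means larger coordinates, so the window is
    ``[tss - downstream, tss + upstream)``.  Windows running past the scaffold
    origin are clipped at 0 rather than dropped, so every valid transcript
    yields exactly one region.  Records with an unknown strand symbol are
    rejected with a diagnostic.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be non-negative")
    if upstream + downstream <= 0:
        raise ValueError("window must have positive width (upstream + downstream > 0)")

    regions: list[Region] = []
    rejected = 0
    for t in transcripts:
        if t.strand == "+":
            start, end = t.tss - upstream, t.tss + downstream
        elif t.strand == "-":
            start, end = t.tss - downstream, t.tss + upstream
        else:
            rejected += 1
            logger.warning(
                "rejecting transcript %s: unknown strand %r", t.transcript_id, t.strand
            )
            continue
        start = max(start, 0)
        if end <= 0:
            # window entirely off the scaffold; keep a degenerate-safe clip
            rejected += 1
            logger.warning(
                "rejecting transcript %s: window [%d, %d) lies before scaffold origin",
                t.transcript_id,
                start,
                end,
            )
            continue
        regions.append(
            Region(t.scaffold, start, end, t.transcript_id, t.gene_id, t.gene_name)
        )
    if rejected:
        logger.warning("rejected %d transcript record(s)", rejected)
    if not regions:
        logger.warning("no valid transcripts: empty region set")
    return RegionSet(regions, (upstream, downstream))


def load_transcript_annotation(path: Union[str, Path]) -> list[TranscriptRecord]:
    """Read a transcript annotation TSV.

    Required columns: scaffold, tss, strand, transcript_id, gene_id;
    optional: gene_name.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["scaffold", "tss", "strand", "transcript_id", "gene_id"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing column {col} in annotation file {path}")
    has_name = "gene_name" in df.columns
    records = []
    for row in df.itertuples(index=False):
        name = getattr(row, "gene_name", None) if has_name else None
        if pd.isna(name):
            name = None
        records.append(
            TranscriptRecord(
                scaffold=row.scaffold,
                tss=int(row.tss),
                strand=row.strand,
                transcript_id=row.transcript_id,
                gene_id=row.gene_id,
                gene_name=name,
            )
        )
    return records


def load_region_file(path: Union[str, Path]) -> RegionSet:
    """Load a user-provided region file (TSV with header).

    Mandatory columns: scaffold, start, end, transcript_id, gene_id.  Rows are
    preserved in file order and used verbatim (no window arithmetic).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in REGION_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column {col}")
    has_name = "gene_name" in df.columns
    regions = []
    for i, row in enumerate(df.itertuples(index=False)):
        start, end = int(row.start), int(row.end)
        if start >= end:
            raise ValueError(
                f"row {i + 1} of {path}: start ({start}) >= end ({end})"
            )
        name = getattr(row, "gene_name", None) if has_name else None
        if pd.isna(name):
            name = None
        regions.append(
            Region(row.scaffold, start, end, row.transcript_id, row.gene_id, name)
        )
    return RegionSet(regions, USER_PROVIDED)


def write_region_file(regions: RegionSet, path: Union[str, Path]) -> None:
    """Write a region set as a TSV that :func:`load_region_file` reads back.

    The gene_name column is emitted only when at least one region carries a
    name.  Writing then loading is the identity on region content.
    """
    rows = []
    any_name = any(r.gene_name is not None for r in regions)
    for r in regions:
        row = {
            "scaffold": r.scaffold,
            "start": r.start,
            "end": r.end,
            "transcript_id": r.transcript_id,
            "gene_id": r.gene_id,
        }
        if any_name:
            row["gene_name"] = r.gene_name if r.gene_name is not None else ""
        rows.append(row)
    cols = REGION_COLUMNS + (["gene_name"] if any_name else [])
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, sep="\t", index=False)
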