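"""Motif catalog resolution: newest versions, heterodimers, human homologs.

The catalog starts from all vertebrate motif records (accession + version +
TF name + species tag).  Initialization keeps only the newest version of each
motif accession, optionally removes heterodimer motifs (named with the
``::`` separator, e.g. ``FOS::JUN``), and resolves non-human TFs to their
human homologs: if the human motif already exists in the catalog the human
version is preferred and the vertebrate record is dropped; if a homolog name
exists but no human motif does, the vertebrate record is renamed to the human
symbol; vertebrate TFs with no known homolog are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

logger = logging.getLogger(__name__)

HETERODIMER_SEPARATOR = "::"
HUMAN_TAG = "human"


@dataclass(frozen=True)
class MotifRecord:
    """One motif: accession without version, version number, TF name, species tag."""

    base_id: str
    version: int
    tf_name: str
    species_tag: str  # "human" or any other-vertebrate tag

    @property
    def motif_id(self) -> str:
        return f"{self.base_id}.{self.version}"

    @property
    def is_human(self) -> bool:
        return self.species_tag == HUMAN_TAG

    @property
    def is_heterodimer(self) -> bool:
        return HETERODIMER_SEPARATOR in self.tf_name


@dataclass
class MotifCatalog:
    """Motif records plus the ordered list of filters already applied."""

    records: list[MotifRecord] = field(default_factory=list)
    filters_applied: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def tf_names(self) -> set[str]:
        return {r.tf_name for r in self.records}

    def by_tf_name(self) -> dict[str, list[MotifRecord]]:
        out: dict[str, list[MotifRecord]] = {}
        for r in self.records:
            out.setdefault(r.tf_name, []).append(r)
        return out


@dataclass
class HomologReport:
    """What happened to each non-human record during homolog resolution."""

    renamed: dict[str, str] = field(default_factory=dict)  # old tf -> human name
    dropped_human_preferred: list[str] = field(default_factory=list)
    discarded_no_homolog: list[str] = field(default_factory=list)
    collisions: list[str] = field(default_factory=list)


def _canonical_sorted(records: Iterable[MotifRecord]) -> list[MotifRecord]:
    return sorted(records, key=lambda r: (r.base_id, r.version, r.tf_name))


def select_newest_versions(records: Iterable[MotifRecord]) -> MotifCatalog:
    """Keep only the maximal-version record of every motif accession.

    Duplicate (base_id, version) pairs indicate a malformed catalog and raise.
    Idempotent: applying it to its own output is the identity.
    """
    seen: set[tuple[str, int]] = set()
    newest: dict[str, MotifRecord] = {}
    for r in records:
        key = (r.base_id, r.version)
        if key in seen:
            raise ValueError(f"duplicate motif record {r.base_id}.{r.version}")
        seen.add(key)
        cur = newest.get(r.base_id)
        if cur is None or r.version > cur.version:
            newest[r.base_id] = r
    return MotifCatalog(_canonical_sorted(newest.values()), ["newest_versions"])


def filter_heterodimers(catalog: MotifCatalog, drop: bool = True) -> MotifCatalog:
    """Optionally remove heterodimer motifs (TF name contains ``::``)."""
    if not drop:
        return MotifCatalog(list(catalog.records), list(catalog.filters_applied))
    kept = [r for r in catalog.records if not r.is_heterodimer]
    n_dropped = len(catalog.records) - len(kept)
    if n_dropped:
        logger.info("dropped %d heterodimer motif(s)", n_dropped)
    return MotifCatalog(kept, list(catalog.filters_applied) + ["drop_heterodimers"])


def _prefer(a: MotifRecord, b: MotifRecord) -> MotifRecord:
    """Collision rule: newest version first, then lexicographically smallest base_id."""
    if a.version != b.version:
        return a if a.version > b.version else b
    return a if a.base_id < b.base_id else b


def resolve_homologs(
    catalog: MotifCatalog,
    homolog_map: Mapping[str, str],
    human_tf_names: Optional[set[str]] = None,
) -> tuple[MotifCatalog, HomologReport]:
    """Resolve vertebrate TF records to human symbols.

    TF names are uppercased on both sides before matching (human TF symbols
    are conventionally uppercase).  ``human_tf_names`` defaults to the names
    of the human-tagged records already in the catalog.  Human records pass
    through untouched; two vertebrate records resolving to the same human
    name keep the preferred one (newest version, then smallest accession) and
    the collision is logged.  The returned catalog has at most one record per
    resolved TF name.
    """
    norm_map = {str(k).upper(): str(v).upper() for k, v in homolog_map.items()}
    human_records: dict[str, MotifRecord] = {}
    report = HomologReport()

    for r in catalog.records:
        if r.is_human:
            name = r.tf_name.upper()
            rec = replace(r, tf_name=name)
            if name in human_records:
                report.collisions.append(name)
                logger.warning("duplicate human motif for %s; keeping preferred", name)
                human_records[name] = _prefer(human_records[name], rec)
            else:
                human_records[name] = rec

    resolved: dict[str, MotifRecord] = dict(human_records)
    known_human = set(human_tf_names or ()) | set(human_records)

    for r in catalog.records:
        if r.is_human:
            continue
        src = r.tf_name.upper()
        target = norm_map.get(src)
        if target is None:
            report.discarded_no_homolog.append(r.tf_name)
            continue
        if target in human_records:
            # the human version of this motif is already present: prefer it
            report.dropped_human_preferred.append(r.tf_name)
            continue
        renamed = replace(r, tf_name=target, species_tag=r.species_tag)
        if target in resolved:
            report.collisions.append(target)
            logger.warning(
                "homolog collision on %s between %s and %s",
                target,
                resolved[target].motif_id,
                renamed.motif_id,
            )
            resolved[target] = _prefer(resolved[target], renamed)
        else:
            report.renamed[r.tf_name] = target
            resolved[target] = renamed
    _ = known_human  # reserved for callers supplying an external human symbol list

    out = MotifCatalog(
        _canonical_sorted(resolved.values()),
        list(catalog.filters_applied) + ["resolve_homologs"],
    )
    return out, report


def initialize_catalog(
    records: Iterable[MotifRecord],
    homolog_map: Mapping[str, str],
    drop_heterodimers: bool = True,
) -> tuple[MotifCatalog, HomologReport]:
    """The full initialization chain: newest versions -> heterodimer filter ->
    homolog resolution.  After it, every entry has a unique human TF name."""
    catalog = select_newest_versions(records)
    catalog = filter_heterodimers(catalog, drop=drop_heterodimers)
    return resolve_homologs(catalog, homolog_map)


def load_motif_catalog(path: Union[str, Path]) -> list[MotifRecord]:
    """Read a motif catalog TSV with columns base_id, version, tf_name, species_tag."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("base_id", "version", "tf_name", "species_tag"):
        if col not in df.columns:
            raise ValueError(f"missing column {col} in motif catalog {path}")
    return [
        MotifRecord(row.base_id, int(row.version), row.tf_name, row.species_tag)
        for row in df.itertuples(index=False)
    ]


def load_homolog_map(path: Union[str, Path]) -> dict[str, str]:
    """Read a homolog map TSV with columns source_name, human_name."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("source_name", "human_name"):
        if col not in df.columns:
            raise ValueError(f"missing column {col} in homolog map {path}")
    return dict(zip(df["source_name"], df["human_name"]))
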