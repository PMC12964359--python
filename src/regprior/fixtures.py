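"""Synthetic, internally consistent input bundles with planted ground truth.

The generator emits every file the pipeline consumes — transcript
annotation, motif catalog, homolog map, gene ID/name map, binding-site
tracks in both layouts (one genome-wide file and one file per TF), and a
STRING-dialect interaction table — built around a planted TF -> gene edge
list.  Construction guarantees exact recovery: every planted edge has at
least one site with a passing score inside a promoter window of that gene,
and background sites either avoid all windows or score below the threshold
(chosen per site with a fixed ratio so both rejection paths are exercised).

Genes are laid out on "chr<N>" scaffolds with enough spacing that promoter
windows of different genes never overlap, which is what makes recovery
exact rather than approximate.  Identical seeds yield byte-identical file
bundles.

The catalog additionally carries inert decoy records — an outdated motif
version, a heterodimer, a vertebrate motif whose human version exists, and
a vertebrate motif with no homolog — so the initialization chain is
exercised end to end without affecting the planted truth (decoys have no
binding sites).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .regions import DEFAULT_DOWNSTREAM, DEFAULT_UPSTREAM
from .sites import DEFAULT_SCORE_THRESHOLD

SITE_LENGTH = 10
GENE_SLOT_SPACING = 4_000  # > 2 * max window extent: windows never collide
FIRST_TSS = 2_000
BACKGROUND_LOW_SCORE_RATIO = 0.5
MAX_PLACEMENT_TRIES = 1_000


@dataclass
class FixtureSpec:
    """Parameters of a synthetic input bundle.

    Score ranges are (min, max) inclusive; the passing range must start at
    or above the threshold the pipeline will use and the failing range must
    stay strictly below it.
    """

    n_scaffolds: int = 3
    n_genes: int = 200
    transcripts_per_gene: int = 2
    n_tfs: int = 20
    n_planted_edges: int = 500
    planted_edges: Optional[set[tuple[str, str]]] = None
    background_site_rate: float = 0.05  # sites per kb of scaffold
    score_passing: tuple[int, int] = (DEFAULT_SCORE_THRESHOLD, 1000)
    score_failing: tuple[int, int] = (50, DEFAULT_SCORE_THRESHOLD - 1)
    upstream: int = DEFAULT_UPSTREAM
    downstream: int = DEFAULT_DOWNSTREAM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.score_failing[1] >= self.score_passing[0]:
            raise ValueError("failing score range overlaps passing range")

    @property
    def tf_names(self) -> list[str]:
        return [f"TF{i:02d}" for i in range(1, self.n_tfs + 1)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]


@dataclass
class FixtureBundle:
    """Paths of a generated bundle plus the planted ground truth."""

    out_dir: Path
    annotation: Path
    motif_catalog: Path
    homolog_map: Path
    gene_name_map: Path
    sites_track: Path
    sites_by_tf_dir: Path
    interactions: Path
    truth_file: Path
    truth_edges: set[tuple[str, str]] = field(default_factory=set)
    spec: Optional[FixtureSpec] = None


def _gene_layout(spec: FixtureSpec, rng: np.random.Generator):
    """Assign each gene a scaffold, strand and transcript TSS positions."""
    scaffolds = [f"chr{i}" for i in range(1, spec.n_scaffolds + 1)]
    rows = []
    per_scaffold_counts = {s: 0 for s in scaffolds}
    strands = rng.choice(["+", "-"], size=spec.n_genes)
    for gi, gene_id in enumerate(spec.gene_ids):
        scaffold = scaffolds[gi % spec.n_scaffolds]
        slot = per_scaffold_counts[scaffold]
        per_scaffold_counts[scaffold] += 1
        base_tss = FIRST_TSS + slot * GENE_SLOT_SPACING
        for tj in range(spec.transcripts_per_gene):
            rows.append(
                {
                    "scaffold": scaffold,
                    "tss": base_tss + tj * 100,
                    "strand": strands[gi],
                    "transcript_id": f"T{gi + 1:04d}.{tj + 1}",
                    "gene_id": gene_id,
                    "gene_name": f"GENE{gi + 1:04d}",
                }
            )
    annotation = pd.DataFrame(rows)
    lengths = {
        s: FIRST_TSS + per_scaffold_counts[s] * GENE_SLOT_SPACING + GENE_SLOT_SPACING
        for s in scaffolds
    }
    return annotation, lengths


def _window(tss: int, strand: str, spec: FixtureSpec) -> tuple[int, int]:
    if strand == "+":
        return max(tss - spec.upstream, 0), tss + spec.downstream
    return max(tss - spec.downstream, 0), tss + spec.upstream


def _all_windows(annotation: pd.DataFrame, spec: FixtureSpec) -> dict[str, list]:
    wins: dict[str, list[tuple[int, int]]] = {}
    for row in annotation.itertuples(index=False):
        wins.setdefault(row.scaffold, []).append(
            _window(row.tss, row.strand, spec)
        )
    for s in wins:
        wins[s].sort()
    return wins


def _overlaps_any(windows: list[tuple[int, int]], start: int, end: int) -> bool:
    return any(ws < end and start < we for ws, we in windows)


def _write_tracks(
    sites: pd.DataFrame, track_path: Path, by_tf_dir: Optional[Path]
) -> None:
    """Write the genome-wide track and, optionally, per-TF tracks of the
    identical site set.  Deterministic sort for byte-stable output."""
    sites = sites.sort_values(
        ["scaffold", "start", "end", "tf_name", "score"], kind="mergesort"
    )
    sites.to_csv(track_path, sep="\t", header=False, index=False)
    if by_tf_dir is not None:
        by_tf_dir.mkdir(parents=True, exist_ok=True)
        for tf, group in sites.groupby("tf_name", sort=True):
            group.to_csv(by_tf_dir / f"{tf}.bed", sep="\t", header=False, index=False)


def generate_fixture(spec: FixtureSpec, out_dir: Union[str, Path]) -> FixtureBundle:
    """Generate a complete input bundle under ``out_dir``.

    Raises if background placement cannot find window-free positions after
    bounded retries (pathologically dense window layouts).
    """
    rng = np.random.default_rng(spec.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    annotation, scaffold_lengths = _gene_layout(spec, rng)
    windows = _all_windows(annotation, spec)

    # planted edges
    if spec.planted_edges is not None:
        planted = sorted(spec.planted_edges)
        known = set(spec.tf_names), set(spec.gene_ids)
        for tf, gene in planted:
            if tf not in known[0] or gene not in known[1]:
                raise ValueError(f"planted edge ({tf}, {gene}) references unknown TF/gene")
    else:
        n_pairs = spec.n_tfs * spec.n_genes
        if spec.n_planted_edges > n_pairs:
            raise ValueError("more planted edges than TF x gene pairs")
        flat = rng.choice(n_pairs, size=spec.n_planted_edges, replace=False)
        flat.sort()
        planted = [
            (spec.tf_names[i // spec.n_genes], spec.gene_ids[i % spec.n_genes])
            for i in flat
        ]

    transcripts_by_gene = {
        g: grp.reset_index(drop=True) for g, grp in annotation.groupby("gene_id")
    }

    site_rows = []
    for tf, gene in planted:
        tx = transcripts_by_gene[gene]
        pick = tx.iloc[int(rng.integers(len(tx)))]
        ws, we = _window(int(pick.tss), pick.strand, spec)
        start = int(rng.integers(ws, we - SITE_LENGTH + 1))
        score = int(rng.integers(spec.score_passing[0], spec.score_passing[1] + 1))
        site_rows.append((pick.scaffold, start, start + SITE_LENGTH, tf, score))

    # background sites: half score below threshold anywhere, half passing
    # scores rejection-sampled away from every window
    total_kb = sum(scaffold_lengths.values()) / 1000.0
    n_background = int(round(spec.background_site_rate * total_kb))
    scaffold_names = sorted(scaffold_lengths)
    for _ in range(n_background):
        scaffold = scaffold_names[int(rng.integers(len(scaffold_names)))]
        length = scaffold_lengths[scaffold]
        tf = spec.tf_names[int(rng.integers(spec.n_tfs))]
        low_score = rng.random() < BACKGROUND_LOW_SCORE_RATIO
        if low_score:
            start = int(rng.integers(0, length - SITE_LENGTH))
            score = int(rng.integers(spec.score_failing[0], spec.score_failing[1] + 1))
        else:
            for _try in range(MAX_PLACEMENT_TRIES):
                start = int(rng.integers(0, length - SITE_LENGTH))
                if not _overlaps_any(
                    windows.get(scaffold, []), start, start + SITE_LENGTH
                ):
                    break
            else:
                raise RuntimeError(
                    "could not place a background site outside all windows; "
                    "the window layout is too dense for this spec"
                )
            score = int(rng.integers(spec.score_passing[0], spec.score_passing[1] + 1))
        site_rows.append((scaffold, start, start + SITE_LENGTH, tf, score))

    sites = pd.DataFrame(
        site_rows, columns=["scaffold", "start", "end", "tf_name", "score"]
    )

    # motif catalog: current human records for every TF, plus inert decoys
    catalog_rows = [
        {
            "base_id": f"MA{i + 1:04d}",
            "version": 2,
            "tf_name": tf,
            "species_tag": "human",
        }
        for i, tf in enumerate(spec.tf_names)
    ]
    for i in range(min(3, spec.n_tfs)):  # outdated versions of real motifs
        catalog_rows.append(
            {
                "base_id": f"MA{i + 1:04d}",
                "version": 1,
                "tf_name": spec.tf_names[i],
                "species_tag": "human",
            }
        )
    catalog_rows += [
        {"base_id": "MA9001", "version": 1, "tf_name": "DXA::DXB", "species_tag": "human"},
        {"base_id": "MA9002", "version": 1, "tf_name": "Vrt1", "species_tag": "mouse"},
        {"base_id": "MA9003", "version": 1, "tf_name": "Vrt2", "species_tag": "mouse"},
    ]
    homolog_rows = [{"source_name": "Vrt1", "human_name": spec.tf_names[0]}]
    # Vrt2 deliberately absent from the map: it must be discarded

    name_map = annotation[["gene_id", "gene_name"]].drop_duplicates()

    # interactions among the TFs plus rows with foreign proteins (dropped)
    inter_rows = []
    n_inter = 2 * spec.n_tfs
    for _ in range(n_inter):
        a, b = rng.choice(spec.n_tfs, size=2, replace=False)
        inter_rows.append(
            {
                "protein1": spec.tf_names[int(a)],
                "protein2": spec.tf_names[int(b)],
                "combined_score": int(rng.integers(150, 1000)),
            }
        )
    inter_rows.append(
        {"protein1": spec.tf_names[0], "protein2": "NOTATF1", "combined_score": 900}
    )
    interactions = pd.DataFrame(inter_rows)

    truth = pd.DataFrame(sorted(set(planted)), columns=["tf", "gene_id"])

    bundle = FixtureBundle(
        out_dir=out,
        annotation=out / "annotation.tsv",
        motif_catalog=out / "motifs.tsv",
        homolog_map=out / "homologs.tsv",
        gene_name_map=out / "gene_names.tsv",
        sites_track=out / "sites.bed",
        sites_by_tf_dir=out / "sites_by_tf",
        interactions=out / "interactions.tsv",
        truth_file=out / "truth_edges.tsv",
        truth_edges=set(map(tuple, truth.itertuples(index=False))),
        spec=spec,
    )
    annotation.to_csv(bundle.annotation, sep="\t", index=False)
    pd.DataFrame(catalog_rows).to_csv(bundle.motif_catalog, sep="\t", index=False)
    pd.DataFrame(homolog_rows).to_csv(bundle.homolog_map, sep="\t", index=False)
    name_map.to_csv(bundle.gene_name_map, sep="\t", index=False)
    _write_tracks(sites, bundle.sites_track, bundle.sites_by_tf_dir)
    interactions.to_csv(bundle.interactions, sep="\t", index=False)
    truth.to_csv(bundle.truth_file, sep="\t", index=False)
    return bundle


def generate_paired_tracks(
    spec: FixtureSpec,
    shift_per_tf: Mapping[str, int],
    out_dir: Union[str, Path],
    sites_per_tf: int = 20,
    base_score_range: tuple[int, int] = (300, 800),
) -> tuple[Path, Path]:
    """Two track versions whose per-TF score shift is planted exactly.

    Version B contains the same sites as version A with every score moved by
    ``shift_per_tf[tf]`` (0 for unlisted TFs), so the mean-score shift per
    TF equals the planted value exactly.  Shifted scores must stay
    non-negative.
    """
    rng = np.random.default_rng(spec.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _, scaffold_lengths = _gene_layout(spec, rng)
    scaffold_names = sorted(scaffold_lengths)

    rows_a, rows_b = [], []
    for tf in spec.tf_names:
        shift = int(shift_per_tf.get(tf, 0))
        for _ in range(sites_per_tf):
            scaffold = scaffold_names[int(rng.integers(len(scaffold_names)))]
            start = int(rng.integers(0, scaffold_lengths[scaffold] - SITE_LENGTH))
            score = int(rng.integers(base_score_range[0], base_score_range[1] + 1))
            if score + shift < 0:
                raise ValueError(f"shift {shift} for {tf} yields a negative score")
            rows_a.append((scaffold, start, start + SITE_LENGTH, tf, score))
            rows_b.append((scaffold, start, start + SITE_LENGTH, tf, score + shift))

    cols = ["scaffold", "start", "end", "tf_name", "score"]
    path_a, path_b = out / "track_a.bed", out / "track_b.bed"
    _write_tracks(pd.DataFrame(rows_a, columns=cols), path_a, None)
    _write_tracks(pd.DataFrame(rows_b, columns=cols), path_b, None)
    return path_a, path_b
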