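"""End-to-end pipeline: initialization -> motif stage -> PPI stage.

:class:`RunConfig` holds every tunable with its default (promoter window
750 bases upstream / 250 downstream of the TSS, minimum match score 400,
heterodimer filtering on).  :func:`run_generate` executes the three stages
in order, writes the motif and PPI priors, and records the provenance of
every input file; on any hard error the partial outputs are removed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional, Union

import yaml

from . import compare as _compare
from . import grn, motifs, ppi, provenance, regions, sites

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters, with the tool's defaults."""

    # window and filtering defaults
    upstream: int = regions.DEFAULT_UPSTREAM
    downstream: int = regions.DEFAULT_DOWNSTREAM
    score_threshold: int = sites.DEFAULT_SCORE_THRESHOLD
    drop_heterodimers: bool = True
    track_layout: str = sites.WHOLE_GENOME
    include_self_ppi: bool = True
    rescale_ppi: bool = True
    workers: int = 1
    gene_key_kind: str = grn.GENE_ID

    # input paths (annotation or a ready-made region file; one is required)
    annotation: Optional[str] = None
    region_file: Optional[str] = None
    motif_catalog: Optional[str] = None
    homolog_map: Optional[str] = None
    gene_name_map: Optional[str] = None
    sites_track: Optional[str] = None  # file (whole-genome) or directory (per-TF)
    interactions: Optional[str] = None

    # output paths
    out_motif_prior: str = "motif_prior.tsv"
    out_ppi_prior: str = "ppi_prior.tsv"
    cache_dir: str = ".regprior_cache"

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def dump_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_sources(
        cls,
        config_file: Optional[Union[str, Path]] = None,
        **overrides: Any,
    ) -> "RunConfig":
        """Build a config from an optional YAML file plus overrides.

        Explicit overrides (CLI flags) win over file values, which win over
        defaults.  Unknown keys in the file are an error.
        """
        values: dict[str, Any] = {}
        if config_file is not None:
            loaded = yaml.safe_load(Path(config_file).read_text()) or {}
            known = {f.name for f in dataclasses.fields(cls)}
            unknown = set(loaded) - known
            if unknown:
                raise ValueError(f"unknown config keys: {sorted(unknown)}")
            values.update(loaded)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


def _require(path: Optional[str], what: str) -> Path:
    if path is None:
        raise ValueError(f"no {what} configured")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} not found: {p}")
    return p


def run_generate(config: RunConfig) -> tuple[grn.MotifPriorEdges, ppi.PPIEdges]:
    """Run the full pipeline and write both priors.

    Returns the in-memory motif prior and PPI prior.  Any stage error
    removes partial output files before propagating.
    """
    outputs = [Path(config.out_motif_prior), Path(config.out_ppi_prior)]
    try:
        return _run_generate(config)
    except Exception:
        for out in outputs:
            if out.exists():
                out.unlink()
                logger.warning("removed partial output %s", out)
        raise


def _run_generate(config: RunConfig) -> tuple[grn.MotifPriorEdges, ppi.PPIEdges]:
    ledger = provenance.default_ledger_path(config.cache_dir)

    # regions of interest
    if config.region_file is not None:
        region_path = _require(config.region_file, "region file")
        provenance.record_input_file(ledger, "region_file", region_path)
        region_set = regions.load_region_file(region_path)
    else:
        ann_path = _require(config.annotation, "transcript annotation")
        provenance.record_input_file(ledger, "annotation", ann_path)
        transcripts = regions.load_transcript_annotation(ann_path)
        region_set = regions.build_promoter_regions(
            transcripts, config.upstream, config.downstream
        )

    # initialization: motif catalog resolution
    catalog_path = _require(config.motif_catalog, "motif catalog")
    provenance.record_input_file(ledger, "motif_catalog", catalog_path)
    records = motifs.load_motif_catalog(catalog_path)
    homolog_map: dict[str, str] = {}
    if config.homolog_map is not None:
        hom_path = _require(config.homolog_map, "homolog map")
        provenance.record_input_file(ledger, "homolog_map", hom_path)
        homolog_map = motifs.load_homolog_map(hom_path)
    catalog, report = motifs.initialize_catalog(
        records, homolog_map, drop_heterodimers=config.drop_heterodimers
    )
    logger.info(
        "catalog: %d TFs (%d renamed to human symbols, %d discarded)",
        len(catalog),
        len(report.renamed),
        len(report.discarded_no_homolog),
    )

    # motif stage
    track_path = _require(config.sites_track, "binding-site track")
    label = "sites_track" if config.track_layout == sites.WHOLE_GENOME else None
    if label:
        provenance.record_input_file(ledger, label, track_path)
    else:
        for tf, p in sorted(sites.per_tf_tracks(track_path).items()):
            provenance.record_input_file(ledger, f"sites_track:{tf}", p)
    matches = sites.process_sharded(
        regions=region_set,
        tracks=str(track_path),
        layout=config.track_layout,
        score_threshold=config.score_threshold,
        workers=config.workers,
        tf_filter=catalog.tf_names,
    )

    # postprocessing into the motif prior
    prior = grn.aggregate_to_genes(matches)
    if config.gene_key_kind == grn.GENE_NAME:
        map_path = _require(config.gene_name_map, "gene name map")
        provenance.record_input_file(ledger, "gene_name_map", map_path)
        prior = grn.convert_ids_to_names(prior, grn.load_id_name_map(map_path))
    grn.write_motif_prior(prior, config.out_motif_prior)
    logger.info(
        "motif prior: %d edges over %d TFs", len(prior), len(prior.tf_names)
    )

    # PPI stage: interactions among the TFs present in the motif prior
    inter_path = _require(config.interactions, "interaction table")
    provenance.record_input_file(ledger, "interactions", inter_path)
    interactions = ppi.load_interactions(inter_path)
    ppi_prior = ppi.build_ppi(
        prior.tf_names,
        interactions,
        include_self=config.include_self_ppi,
        rescale=config.rescale_ppi,
    )
    ppi.write_ppi_prior(ppi_prior, config.out_ppi_prior)
    logger.info("PPI prior: %d edges", len(ppi_prior))
    return prior, ppi_prior


def compare_priors(
    path_a: Union[str, Path],
    path_b: Union[str, Path],
    gene_key_kind: str = grn.GENE_ID,
) -> _compare.ConfusionMatrix:
    """Edge confusion matrix between two motif prior files."""
    a = grn.read_motif_prior(path_a, gene_key_kind)
    b = grn.read_motif_prior(path_b, gene_key_kind)
    return _compare.edge_confusion(a, b)


def compare_tracks(
    path_old: Union[str, Path],
    path_new: Union[str, Path],
    restriction: Optional[set[str]] = None,
) -> _compare.ScoreShift:
    """Per-TF mean score shift between two binding-site track files."""
    return _compare.score_shift(
        sites.read_sites(path_old),
        sites.read_sites(path_new),
        restriction=restriction,
    )
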