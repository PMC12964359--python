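# Methods

## Problem and model

Network-inference algorithms of the PANDA family refine a *prior* gene
regulatory network — a sparse TF → gene edge list encoding where each
transcription factor could plausibly bind — together with a TF–TF
protein–protein interaction (PPI) prior, against experimental expression
data.  `regprior` constructs both priors from four file-based inputs:

1. a transcript annotation (or a ready-made region file, e.g. enhancers),
2. a motif catalog (accession, version, TF name, species tag),
3. precomputed genome-wide TF binding-site tracks with match scores,
4. a STRING-dialect protein-interaction table.

The pipeline has three stages, run in order by `run_generate`:

**Initialization (catalog resolution).**  For every motif accession only
the newest version is kept; heterodimer motifs (JASPAR's `::` naming
convention, e.g. `FOS::JUN`) are optionally removed (on by default);
non-human vertebrate motifs are resolved to human symbols through a
homolog map.  If the human motif of a homolog is already in the catalog,
the human version is preferred and the vertebrate record is dropped;
vertebrate motifs with no homolog are discarded.  Motif conservation
across vertebrates is the biological justification for borrowing
non-human motifs at all.  TF symbols are uppercased on both sides before
matching, since human gene symbols are conventionally uppercase.

**Motif stage (binding-site filtering).**  Regions of interest default to
promoter windows spanning 750 bases upstream to 250 bases downstream of
each transcript's TSS; *upstream* is strand-relative, so on the − strand
the window is `[tss − 250, tss + 750)`.  All coordinates are 0-based
half-open (BED convention), matching the input tracks.  A site matches a
region iff the half-open intervals share ≥ 1 base; requiring full
containment would silently lose sites straddling window edges.  Per
(region, TF) only the best-scoring site is kept, and matches below the
minimum score (default 400, on the JASPAR track score scale) are removed.
Transcript-level matches are then aggregated to genes (an edge exists iff
any transcript of the gene retained a match) with binary weight 1;
absent edges are implicit zeros, so the prior is a sparse, headerless,
deterministically sorted three-column TSV directly usable by PANDA-style
tools.

**PPI stage.**  The TFs present in the motif prior are looked up in the
interaction table; edges with both endpoints in that set are kept,
combined scores are rescaled to [0, 1] by /1000 (switchable), symmetric
duplicate rows collapse to the maximum, and self-edges are added at
weight 1.0 by default (the convention of common PANDA PPI priors).

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `upstream` | 750 | bases | standard promoter-proximal window |
| `downstream` | 250 | bases | captures TSS-proximal binding |
| `score_threshold` | 400 | track score units | conventional cutoff on the JASPAR scale; too high a cutoff would exclude TFs with short motifs whose maximum score is low |
| `drop_heterodimers` | on | — | heterodimer motifs duplicate monomer signals in TF-keyed priors; switchable |
| `include_self_ppi` | on | — | PANDA PPI priors carry unit diagonals |
| `workers` | 1 | processes | sharded by scaffold; the result is provably invariant to worker count |

## Deterministic tie-breaks and numerics

- Best-hit score ties break by smaller start, then smaller end — the
  result is independent of site order, shard partition and track layout.
- When several gene IDs share a gene name, the ID with the most distinct
  TF partners keeps its edges ("number of TF binding sites" after best-hit
  collapsing equals the number of distinct TF partners); ties break by
  lexicographically smaller ID and are logged.  Using gene IDs throughout
  (`gene_key_kind: gene_id`, the default) avoids the issue entirely.
- Homolog collisions (two vertebrate motifs resolving to the same human
  symbol with no human record) keep the newest version, then the smallest
  accession.
- Outputs are canonically sorted, so re-running on unchanged inputs is
  byte-idempotent and priors are diffable.
- The per-TF score shift between two track versions is the difference of
  per-TF mean scores (new − old).  When both versions have the same number
  of sites for a TF it is computed as `(Σnew − Σold)/n`, which is
  algebraically identical but exact in floating point for uniform shifts.
  Sites are compared as distributions, not matched pairs, because motif
  trimming between database releases changes site coordinates.
- The confusion matrix between two priors is restricted to TFs present in
  both; the gene universe is the union of genes in either prior, so genes
  gained or lost between versions register as disagreement.

## Degenerate inputs

Promoter windows running past the scaffold origin are clipped at 0, not
dropped, preserving one region per transcript.  Malformed track rows are
skipped and counted, never fatal.  An empty annotation yields an empty
region set with a warning; an empty TF set is a hard error in the PPI
stage.  A corrupt provenance ledger is renamed aside and restarted.
Scaffolds present in a track but absent from the regions are ignored.

## Provenance

Every input file is recorded in a hidden JSON-lines ledger
(`.provenance.jsonl` in the cache directory): label, source, version, UTC
ISO-8601 retrieval time and SHA-256 content checksum.  Each label keeps
its full history, latest first, so updates are auditable; content hashes
(not modification times) decide whether a reused file changed.
User-provided files are recorded with version "unknown" — their
provenance cannot be known.  A `Fetcher` protocol defines the plug-in
point for remote retrieval; no network client ships with the package.

## The synthetic-data generator

`fixtures.generate_fixture` emits a fully consistent input bundle with a
*planted* TF → gene edge list: genes are spaced 4 kb apart on `chr<N>`
scaffolds so promoter windows of different genes never overlap, each
planted edge gets at least one passing-score site inside a window of that
gene, and background sites are split (50/50) between sub-threshold scores
placed anywhere and passing scores rejection-sampled away from every
window — exercising both rejection paths of the filter.  Both track
layouts are written from the same site set, and identical seeds yield
byte-identical bundles.  Default sizes (3 scaffolds, 200 genes x 2
transcripts, 20 TFs, 500 planted edges, 0.05 background sites/kb, passing
scores 400–1000, failing 50–399) keep a full pipeline run under a second
while leaving the edge density realistic for a prior restricted to a
small TF panel.

What the generator does *not* emulate: real motif-score distributions,
overlapping promoters of distinct genes, enhancer-mediated regulation,
sequence content (the pipeline is purely coordinate-based) and the scale
of a real genome-wide track.  Exact planted-edge recovery on fixtures
therefore demonstrates the correctness of the filtering logic, not the
biological fidelity of any particular prior; on real tracks the edge set
is known to over-predict binding, which is precisely why these networks
are used as *priors* for data-driven refinement rather than as final
GRNs.

## Design choices on genuinely open points

- Coordinate convention (0-based half-open) and the ≥ 1-base overlap rule
  were fixed to the BED dialect of the input tracks.
- The initialization order is version selection → heterodimer filter →
  homolog resolution.
- Whole-genome and per-TF track layouts are promoted to a *tested
  equivalence contract* rather than a mere speed trade-off.
- PPI weights are written rescaled to [0, 1]; a flag restores raw
  0–1000 scores.
- Heterodimer filtering defaults to on, with `--keep-heterodimers` to
  disable.
- Binding-site strand is ignored for overlap: promoter windows accept
  motifs on either strand.

## Known limitations

Only file-based inputs are supported (the fetcher plug-in point exists
but no client is included); bigbed tracks must be exported to the BED
TSV dialect first; non-human genomes are untested beyond the homolog
mapping path; score thresholds are global, not per-TF, so TFs with short
motifs are disadvantaged at high cutoffs.
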