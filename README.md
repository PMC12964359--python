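# regprior

Prior network generation for gene regulatory network (GRN) inference.

Algorithms of the PANDA family ("Passing Attributes between Networks for
Data Assimilation") integrate three inputs: a **motif prior** — a sparse
TF → gene edge list marking where each transcription factor (TF) has a
predicted binding site near a gene — a **TF–TF protein–protein interaction
(PPI) prior**, and expression data.  The quality of the inferred GRN
depends directly on those priors, yet they are tedious to rebuild as the
underlying databases update, so stale priors tend to circulate for years.

`regprior` builds both priors reproducibly from plain-text inputs:

- a transcript annotation (or a user region file, e.g. enhancer calls),
- a versioned motif catalog with species tags and a vertebrate → human
  homolog map,
- precomputed genome-wide TF binding-site tracks (BED5-dialect TSV:
  chrom, start, end, TF, score), either one genome-wide file or one file
  per TF,
- a STRING-dialect interaction table (protein1, protein2,
  combined_score on the 0–1000 scale).

The pipeline: (1) **initialization** — keep the newest version of each
motif, optionally drop heterodimers (`::` names), resolve vertebrate TFs
to human symbols (the human motif wins when both exist; unmapped
vertebrate motifs are discarded); (2) **motif stage** — intersect the
tracks with promoter windows (default 750 bp upstream to 250 bp
downstream of each TSS, strand-aware, BED coordinates), keep the single
best-scoring site per (region, TF), drop matches scoring below 400, and
aggregate transcripts into genes; (3) **PPI stage** — restrict the
interaction table to the TFs present in the motif prior, rescale scores
to [0, 1].  Every input file's checksum, version and retrieval time is
recorded in a hidden provenance ledger, and a comparison toolkit
quantifies how priors change between database releases (edge confusion
matrix over shared TFs; per-TF score shifts between track versions).

Processing is sharded by chromosome and can run in parallel; the output
is provably identical for any worker count, shard partition, and for
both track layouts.  See `docs/methods.md` for the model, tie-break
rules and limitations.

## Worked example

Everything runs offline; a synthetic bundle generator ships with the
package and plants a known ground-truth edge list:

```sh
regprior fixture --out-dir fx --seed 1 --n-genes 50 --n-tfs 10 --n-planted-edges 120
regprior generate \
    --annotation fx/annotation.tsv --motif-catalog fx/motifs.tsv \
    --homolog-map fx/homologs.tsv --sites-track fx/sites.bed \
    --interactions fx/interactions.tsv \
    --out-motif-prior motif_prior.tsv --out-ppi-prior ppi_prior.tsv \
    --cache-dir cache
```

prints

```
motif prior: 120 edges over 10 TFs -> motif_prior.tsv
PPI prior: 26 edges -> ppi_prior.tsv
```

The 120 recovered edges are exactly the 120 planted ones
(`fx/truth_edges.tsv`): every planted edge has a passing-score site in a
promoter window, and all background sites either miss the windows or
fall below the score threshold.  The priors are PANDA-ready headerless
TSVs:

```
$ head -3 motif_prior.tsv          $ head -3 ppi_prior.tsv
TF01    G0004   1                  TF01    TF01    1.000
TF01    G0012   1                  TF01    TF02    0.414
TF01    G0016   1                  TF01    TF03    0.492
```

Comparing a prior with itself gives a clean diagonal, and the provenance
ledger lists what went into the run:

```
$ regprior compare --prior-a motif_prior.tsv --prior-b motif_prior.tsv --out report.json
shared TFs: 10; both: 120; only A: 0; only B: 0; disagreement: 0.0000
$ regprior provenance --cache-dir cache
annotation  source=user-provided  version=unknown  retrieved=user-provided  sha256=96e9b87e4771
...
```

`regprior config` dumps the effective configuration (upstream 750,
downstream 250, score_threshold 400, ...); the same keys can be set in a
YAML file passed via `--config`, with flags taking precedence.

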