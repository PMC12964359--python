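import pytest

from regprior import FixtureSpec, RunConfig, generate_fixture


SMALL_SPEC = dict(n_scaffolds=2, n_genes=25, transcripts_per_gene=2, n_tfs=6,
                  n_planted_edges=40, background_site_rate=0.05)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small synthetic input bundle shared across tests (read-only)."""
    out = tmp_path_factory.mktemp("bundle")
    return generate_fixture(FixtureSpec(seed=7, **SMALL_SPEC), out)


def config_for(bundle, out_dir, **overrides):
    """RunConfig wired to a fixture bundle, outputs under out_dir."""
    base = dict(
        annotation=str(bundle.annotation),
        motif_catalog=str(bundle.motif_catalog),
        homolog_map=str(bundle.homolog_map),
        gene_name_map=str(bundle.gene_name_map),
        sites_track=str(bundle.sites_track),
        interactions=str(bundle.interactions),
        out_motif_prior=str(out_dir / "motif_prior.tsv"),
        out_ppi_prior=str(out_dir / "ppi_prior.tsv"),
        cache_dir=str(out_dir / "cache"),
    )
    base.update(overrides)
    return RunConfig(**base)
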