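import pandas as pd
import pytest

from hybridase.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic study shared across tests."""
    cfg = SimConfig(n_genes=300, chrom_length=800_000,
                    methyl_region_length=40_000, planted_gdmr_count=10,
                    seed=5)
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_fixtures(small_sim, tmp_path_factory):
    """The small study written out as VCF/GFF3/TSV files."""
    from hybridase.simulate import write_fixtures

    outdir = tmp_path_factory.mktemp("fixtures")
    return write_fixtures(small_sim, outdir)


def make_calls(rows):
    """Build an ASEG call frame from (gene_id, status, genotype) tuples."""
    return pd.DataFrame(
        [(g, "H", "embryo", s, 0.01 if s == "biased" else 0.5,
          9 if s == "biased" else 0, p) for g, s, p in rows],
        columns=["gene_id", "hybrid", "tissue", "status", "q_value",
                 "fold_tier", "preferred_genotype"])
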