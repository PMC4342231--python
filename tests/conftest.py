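import pytest

from delstack import io as dio
from delstack.pipeline import (
    default_control_design,
    homoeologue_sets_from_tables,
    snp_tables_for_samples,
    standard_control_genotypes,
)
from delstack.synthetic_data import SimulationConfig, generate_homoeolog_references


@pytest.fixture(scope="session")
def panel():
    """The packaged 21-marker flanking panel (anchor at offset 0)."""
    return dio.load_marker_panel()


@pytest.fixture(scope="session")
def small_sim(panel):
    """A compact simulated study shared by caller-mechanics tests.

    Six panel genes around the anchor, error-free reads, standard controls
    (two wild types + three nulli-tetras).  Returns (cfg, refs, genotypes,
    snp_tables, homoeologue sets).
    """
    gene_ids = [m.gene_id for m in panel if -100 <= m.offset_kb <= 100]
    cfg = SimulationConfig(n_genes=len(gene_ids), seed=11, error_rate=0.0)
    refs = generate_homoeolog_references(cfg, gene_ids=gene_ids)
    genotypes = standard_control_genotypes(refs.gene_ids)
    tables = snp_tables_for_samples(genotypes, refs, cfg, seed=5)
    sets = homoeologue_sets_from_tables(tables, default_control_design())
    return cfg, refs, genotypes, tables, sets
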