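import pytest

from essevo import phenotype as ph
from essevo import goslim as gs
from essevo import simulate as sim


@pytest.fixture(scope="session")
def mp_ontology(tmp_path_factory):
    path = tmp_path_factory.mktemp("obo") / "mp_toy.obo"
    sim.write_toy_mp_obo(path)
    return ph.MPOntology.from_obo(path)


@pytest.fixture(scope="session")
def go_graph(tmp_path_factory):
    path = tmp_path_factory.mktemp("obo") / "go_toy.obo"
    sim.write_toy_go_obo(path)
    return gs.GOGraph.from_obo(path)


@pytest.fixture(scope="session")
def default_simulation(tmp_path_factory):
    """Default-size simulated study (965 genes) with emitted fixture files."""
    out = tmp_path_factory.mktemp("sim") / "fixtures"
    gt = sim.simulate_gene_table(sim.SimulationConfig(seed=7))
    manifest = sim.emit_fixture_files(gt, out)
    return gt, out, manifest


def make_allele(gene, term, *, allele_id=None, allele_type="Targeted",
                attributes=("Null/knockout",), n_targeted=1,
                zygosity="homozygous", flags=(), x_linked=False):
    """Helper constructing a single-term phenotype allele row."""
    return ph.PhenotypeAlleleRow(
        gene_id=gene,
        allele_id=allele_id or f"{gene}_a",
        allele_type=allele_type,
        allele_attributes=frozenset(attributes),
        n_targeted_genes=n_targeted,
        zygosity=zygosity,
        mp_terms=frozenset([term] if isinstance(term, str) else term),
        curation_flags=frozenset(flags),
        x_linked=x_linked,
    )
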