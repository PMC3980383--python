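import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from heteroprop import (
    FixtureSpec,
    HeteroNetwork,
    HomoNetwork,
    IntegratedNetwork,
    generate_fixture,
    toy_network,
)


@pytest.fixture
def toy():
    """P1-G1-D1 chain with strict small-alpha diffusion."""
    return toy_network("chain")


@pytest.fixture
def small_fixture():
    """A reduced synthetic study that assembles in well under a second."""
    spec = FixtureSpec(
        n_drugs=30, n_genes=80, n_phenotypes=10, module_size=12,
        n_positive_drugs=6, seed=7,
    )
    return generate_fixture(spec)


def permute_network(net: IntegratedNetwork, rng: np.random.Generator) -> tuple[IntegratedNetwork, dict]:
    """Relabel/reorder every node set by a random permutation."""
    perms = {}
    homos = {}
    for kind in ("drug", "gene", "phenotype"):
        homo = net.homo(kind)
        perm = rng.permutation(homo.n_nodes)
        perms[kind] = perm
        homos[kind] = HomoNetwork(
            [homo.node_ids[i] for i in perm],
            homo.weights[np.ix_(perm, perm)],
            kind,
        )
    pd, pg, pp = perms["drug"], perms["gene"], perms["phenotype"]
    dg = net.drug_gene
    pgn = net.phenotype_gene
    permuted = IntegratedNetwork(
        drug=homos["drug"],
        gene=homos["gene"],
        phenotype=homos["phenotype"],
        drug_gene=HeteroNetwork(
            [dg.row_ids[i] for i in pd], [dg.col_ids[j] for j in pg],
            dg.links[np.ix_(pd, pg)],
        ),
        phenotype_gene=HeteroNetwork(
            [pgn.row_ids[i] for i in pp], [pgn.col_ids[j] for j in pg],
            pgn.links[np.ix_(pp, pg)],
        ),
        config=net.config,
    )
    return permuted, perms
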