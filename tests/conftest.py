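import numpy as np
import pytest

import t2tdup as T


@pytest.fixture(scope="session")
def demo_plan():
    return T.GenomePlan(n_chromosomes=4, chrom_length=300_000, seed=11)


@pytest.fixture(scope="session")
def demo(demo_plan):
    """One deterministic synthetic genome shared across the suite."""
    genome, ledger, genes, tes = T.generate_genome(demo_plan)
    return {"plan": demo_plan, "genome": genome, "ledger": ledger,
            "genes": genes, "tes": tes}


@pytest.fixture(scope="session")
def demo_expression(demo):
    pairs = demo["ledger"].pair_table()
    counts, tpm, truth = T.simulate_expression(
        pairs, demo["plan"].expression_design,
        background_genes=[g.gene_id for g in demo["genes"]],
        gene_lengths={g.gene_id: g.length for g in demo["genes"]},
        seed=demo["plan"].seed + 1)
    return {"pairs": pairs, "counts": counts, "tpm": tpm, "truth": truth}


@pytest.fixture(scope="session")
def demo_arrays(demo):
    from t2tdup.centromeres import genome_tandem_arrays

    return genome_tandem_arrays(demo["genome"], min_period=50, max_period=500)


@pytest.fixture(scope="session")
def tiny():
    """Single small chromosome without planted duplications."""
    plan = T.GenomePlan(n_chromosomes=1, chrom_length=120_000,
                        cen_array_span=20_000, sd_specs=[],
                        n_gene_pairs=0, n_collinear_blocks=0, seed=6)
    return T.generate_genome(plan)


def random_dna(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
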