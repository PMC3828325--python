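import numpy as np
import pandas as pd
import pytest

from xplatsig import (ProbeLocus, SyntheticConfig, generate_fixture,
                      find_mutual_best_matches, filter_mapping, MappingFilter)


def make_locus(probe_id, center, *, length=50, platform="A", gene="gene1",
               chrom="chr1"):
    """Locus with an integer-center interval at the requested position."""
    start = int(round(center - length / 2))
    return ProbeLocus(probe_id=probe_id, platform_id=platform, chrom=chrom,
                      start=start, end=start + length, strand="+",
                      gene_id=gene)


def random_loci(rng, n, platform, *, n_genes=20, span=300_000):
    """Random probe set for oracle-equivalence tests."""
    loci = []
    for i in range(n):
        gene = f"gene{rng.integers(n_genes)}"
        start = int(rng.integers(0, span))
        length = int(rng.integers(25, 400))
        loci.append(ProbeLocus(probe_id=f"{platform}{i:04d}",
                               platform_id=platform, chrom="chr1",
                               start=start, end=start + length,
                               strand="+", gene_id=gene))
    return loci


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down generator config used by the unit tests (fast)."""
    return SyntheticConfig(n_genes=300, n_signature_genes=40, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_fixture(small_config)


@pytest.fixture(scope="session")
def small_mapping(small_bundle):
    table = find_mutual_best_matches(small_bundle.probes_a,
                                     small_bundle.probes_b)
    return filter_mapping(table, MappingFilter())


@pytest.fixture(scope="session")
def mapped_training(small_bundle, small_mapping):
    """Training matrices restricted to the mapped (mutual) probe universe."""
    mut = small_mapping.mutual_pairs()
    return (small_bundle.expr_train_a.loc[mut["probe_a"]],
            small_bundle.expr_train_b.loc[mut["probe_b"]])


@pytest.fixture
def tiny_expression():
    rng = np.random.default_rng(5)
    return pd.DataFrame(rng.uniform(4, 12, size=(6, 4)).round(4),
                        index=[f"p{i}" for i in range(6)],
                        columns=[f"s{i}" for i in range(4)])
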