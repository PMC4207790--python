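import numpy as np
import pytest

from adaptmut import calling, genomes

# Standard fixture: toy 3-chromosome haploid reference (120 kb) with
# 100 planted SNPs in one strain, sequenced at depth 30 / error 0.005.


@pytest.fixture(scope="session")
def ref():
    return genomes.make_reference(n_chrom=3, genes_per_chrom=6, seed=1)


@pytest.fixture(scope="session")
def std_planted(ref):
    assignments = [("s1", "snp")] * 100
    return genomes.plant_mutations(ref, assignments, seed=2)


@pytest.fixture(scope="session")
def std_counts(ref, std_planted):
    tables, tracks = genomes.simulate_counts(
        ref,
        std_planted,
        ["ancestor", "s1", "clean"],
        mean_depth=30.0,
        error_rate=0.005,
        seed=5,
    )
    return tables, tracks


@pytest.fixture(scope="session")
def thresholds():
    return calling.CallerThresholds()


def make_counts(arrays: dict[str, np.ndarray], strain_id: str = "s") -> genomes.NucleotideCountTable:
    """Build a count table from small hand-written (L, 6) arrays."""
    return genomes.NucleotideCountTable(
        strain_id=strain_id,
        counts={c: np.asarray(a, dtype=np.int64) for c, a in arrays.items()},
    )
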