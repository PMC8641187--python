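import numpy as np
import pytest

from sweepkit.genotype_io import GenotypeMatrix, PopulationScheme, VariantLocus
from sweepkit.synthetic_data import BreedSpec, SimConfig, simulate_cohort


def make_matrix(dosage, positions=None, chrom="chr1", populations=None, sample_prefix="s"):
    """Small GenotypeMatrix helper: dosage is samples x loci."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, L = dosage.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(L)]
    loci = [
        VariantLocus(chrom, int(p), f"{chrom}_snp{j+1}", "A", "G")
        for j, p in enumerate(positions)
    ]
    samples = [f"{sample_prefix}{i+1}" for i in range(n)]
    if populations is None:
        pops = {s: "pop1" for s in samples}
    elif isinstance(populations, dict):
        pops = populations
    else:
        pops = {s: p for s, p in zip(samples, populations)}
    return GenotypeMatrix(loci, samples, dosage, pops)


def random_matrix(rng, n_samples=12, n_loci=40, chrom_count=2, missing_rate=0.05, pops=("p1", "p2")):
    """Random multi-chromosome matrix for oracle comparisons."""
    cols = []
    loci = []
    used = set()
    for j in range(n_loci):
        chrom = f"chr{rng.integers(1, chrom_count + 1)}"
        while True:
            pos = int(rng.integers(1, 500_000))
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                break
        p = rng.uniform(0.05, 0.95)
        col = rng.binomial(2, p, size=n_samples).astype(np.int8)
        miss = rng.random(n_samples) < missing_rate
        col[miss] = -1
        cols.append(col)
        loci.append(VariantLocus(chrom, pos, f"r{j}", "A", "G"))
    dosage = np.stack(cols, axis=1)
    samples = [f"s{i}" for i in range(n_samples)]
    populations = {s: pops[i % len(pops)] for i, s in enumerate(samples)}
    return GenotypeMatrix(loci, samples, dosage, populations)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale simulated cohort shared across test modules."""
    cfg = SimConfig(
        n_chromosomes=3,
        chrom_length_bp=5_000_000,
        n_snps=1500,
        breeds=[
            BreedSpec("native_a", "indigenous", 15, 300),
            BreedSpec("native_b", "indigenous", 12, 300),
            BreedSpec("meat_a", "commercial_meat", 14, 150),
            BreedSpec("milk_a", "commercial_milk", 16, 150),
        ],
        n_selected_loci=8,
        seed=11,
    )
    g, truth = simulate_cohort(cfg)
    return cfg, g, truth


@pytest.fixture
def two_group_scheme():
    return PopulationScheme(groups={"grp1": {"p1"}, "grp2": {"p2"}})
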