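import collections

import pytest

from indelkit import simulate as sim


SimBundle = collections.namedtuple(
    "SimBundle", "config genome truth genome_a genome_b f2"
)


@pytest.fixture(scope="session")
def small_config():
    return sim.SimConfig(
        seed=7, n_chromosomes=3, chrom_length_bp=50_000, f2_markers_per_chrom=8
    )


@pytest.fixture(scope="session")
def sim_bundle(small_config):
    genome, truth, ga, gb, f2 = sim.simulate_all(small_config)
    return SimBundle(small_config, genome, truth, ga, gb, f2)


@pytest.fixture(scope="session")
def sim_dir(sim_bundle, tmp_path_factory):
    """The same simulation written out as files (FASTA/VCF/TSV/JSON)."""
    d = tmp_path_factory.mktemp("simdata")
    b = sim_bundle
    sim.write_fasta(b.genome, d / "reference.fasta")
    sim.write_fasta(b.genome_a, d / "parent_a.fasta")
    sim.write_fasta(b.genome_b, d / "parent_b.fasta")
    sim.write_population_vcf(b.truth, b.genome, d / "population.vcf")
    sim.write_genotype_table(b.f2, d / "f2_genotypes.tsv")
    sim.write_physical_positions(b.truth, d / "physical_positions.tsv")
    sim.write_truth_json(b.truth, d / "truth.json")
    return d
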