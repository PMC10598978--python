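import pytest

from cassette_scan.search import Hit
from cassette_scan.simulate import SimConfig, simulate_dataset


def make_hit(**kw):
    """Hit factory with sensible defaults for rule-level tests."""
    defaults = dict(
        query_id="q1",
        query_family="mr10E",
        contig_id="c1",
        genome_id="g1",
        subject_start=0,
        subject_end=300,
        strand="+",
        frame=1,
        percent_identity=90.0,
        query_coverage=95.0,
        alignment_length=100,
        raw_score=500,
        bit_score=200.0,
        evalue=1e-30,
        query_length=100,
    )
    defaults.update(kw)
    if "alignment_length" not in kw:
        span = defaults["subject_end"] - defaults["subject_start"]
        defaults["alignment_length"] = max(100, -(-span // 3))
    return Hit(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    """A small deterministic synthetic dataset shared across tests."""
    return simulate_dataset(SimConfig(n_species=2, strains_per_species=4, seed=11,
                                      contig_length_bp=12_000))


@pytest.fixture(scope="session")
def noiseless_dataset():
    """All divergence off: every implant is an exact copy of the roots."""
    return simulate_dataset(
        SimConfig(n_species=2, strains_per_species=3, seed=5, contig_length_bp=12_000,
                  centroid_divergence_aa=0.0, strain_noise_aa=0.0,
                  p_partial=0.0, p_orphan=0.0, p_cassette=1.0)
    )
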