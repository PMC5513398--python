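import pytest
from hypothesis import HealthCheck, settings

from genestats.analysis import analyze_genome
from genestats.fixtures import FixtureSpec, generate, worked_micro_genome

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def micro_genome(tmp_path_factory):
    """The fixed, hand-auditable 2-scaffold / 3-gene genome."""
    return worked_micro_genome(tmp_path_factory.mktemp("micro"))


@pytest.fixture(scope="session")
def micro_analysis(micro_genome):
    return analyze_genome(str(micro_genome.fasta_path),
                          str(micro_genome.gff3_path), "micro")


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A 30-gene lognormal fixture with recorded ground truth."""
    spec = FixtureSpec(gene_count=30, scs_count=4,
                       scs_length_range=(40_000, 80_000), rng_seed=7)
    return generate(spec, tmp_path_factory.mktemp("fx"), "fx")


@pytest.fixture(scope="session")
def small_analysis(small_fixture):
    return analyze_genome(str(small_fixture.fasta_path),
                          str(small_fixture.gff3_path), "fx")


def assert_matches_truth(overview: dict, truth_overview: dict) -> None:
    """Every ground-truth overview value must be recovered exactly
    (integers/strings) or to 1e-9 (ratios)."""
    for key, expected in truth_overview.items():
        got = overview.get(key, "<missing>")
        if isinstance(expected, float):
            assert got is not None and got == pytest.approx(expected, abs=1e-9), \
                f"{key}: expected {expected}, got {got}"
        else:
            assert got == expected, f"{key}: expected {expected}, got {got}"
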