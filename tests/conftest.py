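import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from plastedit.calling import call_sites
from plastedit.genome import GeneModel, Plastome
from plastedit.pileup import pileup_from_truth
from plastedit.simulate import SimulationConfig, make_plastome, simulate_reads


@pytest.fixture(scope="session")
def sim42():
    """Reference simulation: seed 42, 20 injected sites, 0.1% error."""
    config = SimulationConfig(seed=42)
    plastome, truth = make_plastome(config)
    reads, truth = simulate_reads(plastome, truth, config)
    pileups = pileup_from_truth(reads, plastome)
    return config, plastome, truth, reads, pileups


@pytest.fixture(scope="session")
def sim42_sites(sim42):
    _, plastome, _, _, pileups = sim42
    return call_sites(pileups, plastome, min_coverage=100)


@pytest.fixture
def toy_plastome():
    """Tiny hand-built plastome: one plus gene, one minus gene, one rRNA."""
    #          1        10        20        30        40        50
    # gene A (+) 5..16: ATG CAT TCA TAA ; gene B (-) 25..36; rrn 41..52
    gene_a = "ATGCATTCATAA"
    gene_b_sense = "ATGCCATGGTAA"
    from plastedit.genome import reverse_complement

    seq = (
        "GGGG" + gene_a + "GGGGGGGG" + reverse_complement(gene_b_sense)
        + "CCCC" + "ACGTACGTACGT" + "GG"
    )
    return Plastome(
        seq_id="toy",
        sequence=seq,
        genes=[
            GeneModel("psbA", "+", 5, 16, kind="protein"),
            GeneModel("ndhB", "-", 25, 36, kind="protein"),
            GeneModel("rrn5S", "+", 41, 52, kind="rRNA"),
        ],
    )
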