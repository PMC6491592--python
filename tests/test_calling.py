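"""Editing-site calling: frequency rule, strand handling, spectrum."""

import numpy as np
import pytest

from plastedit.calling import (
    DEFAULT_CONVERSIONS,
    call_sites,
    conversion_content,
    conversion_frequency,
    substitution_spectrum,
)
from plastedit.genome import GeneModel, Plastome
from plastedit.pileup import SitePileup
from plastedit.simulate import (
    SimulationConfig,
    make_plastome,
    simulate_reads,
    truth_compare,
)
from plastedit.pileup import pileup_from_truth


def _site(pos, coverage=None, **counts):
    full = {"A": 0, "C": 0, "G": 0, "T": 0}
    full.update(counts)
    return SitePileup(position=pos, counts=full, coverage=coverage)


@pytest.mark.parametrize(
    "counts,coverage,ref,alt,expected",
    [
        # published per-site counts with their printed total coverage
        ({"C": 39, "T": 187680}, 188389, "C", "T", 0.9962),
        ({"C": 140, "T": 8556}, 8704, "C", "T", 0.983),
        ({"C": 10}, None, "C", "T", 0.0),
    ],
)
def test_conversion_frequency(counts, coverage, ref, alt, expected):
    freqs = conversion_frequency(_site(1, coverage=coverage, **counts), ref)
    assert freqs[alt] == pytest.approx(expected, abs=5e-4)


def test_conversion_frequency_rejects_zero_coverage():
    with pytest.raises(ValueError, match="zero coverage"):
        conversion_frequency(_site(1), "C")


def _one_gene_plastome(strand="+"):
    # plus-strand sequence; gene occupies 1..12
    seq = "ATGCATTCATAA" if strand == "+" else "TTATGAATGCAT"
    return Plastome("p", seq + "GGGG", genes=[GeneModel("g", strand, 1, 12)])


def test_threshold_is_strict():
    plastome = _one_gene_plastome()
    piles = {4: _site(4, C=95, T=5), 5: _site(5, A=947, G=53)}
    # pos 4: freq exactly 0.05 -> not called; pos 5: 0.053 -> called
    sites = call_sites(piles, plastome, min_coverage=1)
    assert [s.position for s in sites] == [5]
    assert sites[0].conversion_gene_strand == "A-to-G"
    assert sites[0].frequency == pytest.approx(0.053)


def test_min_coverage_and_threshold_monotonic():
    plastome = _one_gene_plastome()
    rng = np.random.default_rng(0)
    piles = {}
    for pos in range(1, 13):
        cov = int(rng.integers(5, 500))
        alt = int(rng.integers(0, cov // 3))
        ref = plastome.sequence[pos - 1]
        alt_base = "T" if ref != "T" else "C"
        piles[pos] = _site(pos, **{ref: cov - alt, alt_base: alt})
    counts = []
    for thr in (0.01, 0.05, 0.2, 0.5):
        counts.append(len(call_sites(piles, plastome, threshold=thr,
                                     min_coverage=1, allowed_conversions="all")))
    assert counts == sorted(counts, reverse=True)
    counts = []
    for mc in (1, 10, 100, 1000):
        counts.append(len(call_sites(piles, plastome, min_coverage=mc,
                                     allowed_conversions="all")))
    assert counts == sorted(counts, reverse=True)


def test_bad_threshold_rejected():
    with pytest.raises(ValueError):
        call_sites({}, _one_gene_plastome(), threshold=1.5)


def test_minus_strand_content_is_complement_adjusted():
    """A plus-strand G→A pileup signal under a minus-strand gene is C-to-U."""
    plastome = Plastome(
        "p", "AAAAGAAAAAAA", genes=[GeneModel("g", "-", 1, 12)]
    )
    piles = {5: _site(5, G=60, A=40)}
    (site,) = call_sites(piles, plastome, min_coverage=1)
    assert site.ref_base_plus == "G" and site.edited_base_plus == "A"
    assert site.conversion_gene_strand == "C-to-U"


def test_intergenic_sites_labeled_igs():
    plastome = Plastome("p", "CCCC", genes=[])
    piles = {2: _site(2, C=80, T=20)}
    (site,) = call_sites(piles, plastome, min_coverage=1)
    assert site.region == "IGS" and site.gene is None


def test_default_conversions_exclude_transversions():
    plastome = Plastome("p", "CCCC", genes=[])
    piles = {2: _site(2, C=80, G=20)}  # C-to-G transversion
    assert call_sites(piles, plastome, min_coverage=1) == []
    assert len(call_sites(piles, plastome, min_coverage=1,
                          allowed_conversions="all")) == 1


def test_multi_allelic_flagged_and_highest_reported():
    plastome = Plastome("p", "CCCC", genes=[])
    piles = {2: _site(2, C=60, T=30, A=10)}
    (site,) = call_sites(piles, plastome, min_coverage=1,
                         allowed_conversions="all")
    assert site.edited_base_plus == "T" and site.multi_allelic


def test_strand_mirror_consistency():
    """Mirroring the simulation to the opposite strand preserves the
    gene-strand conversion labels."""
    base = dict(n_genes=6, n_editing_sites=6, n_reads=30000, error_rate=0.0)
    cfg_plus = SimulationConfig(seed=19, strand_fraction_minus=0.0, **base)
    cfg_minus = SimulationConfig(seed=19, strand_fraction_minus=1.0, **base)
    labels = {}
    for key, cfg in (("plus", cfg_plus), ("minus", cfg_minus)):
        plastome, truth = make_plastome(cfg)
        reads, truth = simulate_reads(plastome, truth, cfg)
        sites = call_sites(pileup_from_truth(reads, plastome), plastome,
                           min_coverage=50)
        labels[key] = sorted(
            (s.gene, s.conversion_gene_strand) for s in sites
        )
        sens, fp = truth_compare(sites, truth)
        assert sens == 1.0 and fp == 0
    assert labels["plus"] == labels["minus"]


def test_called_frequency_tracks_injected_fraction(sim42, sim42_sites):
    """Observed frequency lies within 4 binomial standard errors of the
    injected conversion fraction at every site."""
    _, _, truth, _, pileups = sim42
    by_pos = truth.site_by_position()
    for site in sim42_sites:
        injected = by_pos[site.position]
        n = pileups[site.position].coverage
        se = (injected.fraction * (1 - injected.fraction) / n) ** 0.5
        assert abs(site.frequency - injected.fraction) < 4 * se + 1e-9


def test_substitution_spectrum_counts():
    assert substitution_spectrum([]) == {}
    assert substitution_spectrum(["C-to-U", "C-to-U", "U-to-C"]) == {
        "C-to-U": 2,
        "U-to-C": 1,
    }


def test_conversion_content_helper():
    assert conversion_content("C", "T", "+") == "C-to-U"
    assert conversion_content("G", "A", "-") == "C-to-U"
    assert conversion_content("A", "G", "+") == "A-to-G"
    assert conversion_content("T", "C", "+") == "U-to-C"
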