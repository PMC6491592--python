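"""Codon-effect annotation: classes, display strings, exhaustive oracle."""

import itertools

import pytest
from Bio.Seq import Seq

from plastedit.calling import EditingSite, call_sites
from plastedit.codons import (
    annotate_site,
    classify_fixture_row,
    render_display,
    summarize_by_group,
    summarize_spectrum,
)
from plastedit.genome import GeneModel, Plastome, STOP
from plastedit.pileup import pileup_from_truth
from plastedit.pipeline import load_fixture
from plastedit.simulate import SimulationConfig, make_plastome, simulate_reads

RNA = "ACGU"
_DNA = {"A": "A", "C": "C", "G": "G", "U": "T"}


def _site_for(plastome, position, alt_plus):
    ref = plastome.sequence[position - 1]
    gene = plastome.gene_at(position)
    return EditingSite(
        position=position,
        ref_base_plus=ref,
        edited_base_plus=alt_plus,
        gene=gene.name,
        region="coding",
        conversion_gene_strand="",
        frequency=0.5,
        coverage=100,
    )


@pytest.mark.parametrize(
    "codon,pos,alt,aa_b,aa_a,klass",
    [
        ("UCA", 2, "U", "S", "L", "nonsynonymous"),
        ("CCC", 3, "U", "P", "P", "synonymous"),
        ("CAA", 1, "U", "Q", STOP, "stop_gain"),
        ("ACG", 2, "U", "T", "M", "start_gain"),  # codon 1 of the gene
    ],
)
def test_annotate_site_reference_changes(codon, pos, alt, aa_b, aa_a, klass):
    dna = "".join(_DNA[b] for b in codon) + "TAA"
    plastome = Plastome("p", dna, genes=[GeneModel("g", "+", 1, 6)])
    change = annotate_site(_site_for(plastome, pos, _DNA[alt]), plastome)
    assert (change.aa_before, change.aa_after, change.klass) == (aa_b, aa_a, klass)
    assert change.aa_index == 1 and change.codon_pos == pos
    assert change.nt_index == 3 * (change.aa_index - 1) + change.codon_pos


def test_start_gain_requires_first_codon():
    # ACG -> AUG at codon 2 is ordinary nonsynonymous T -> M.
    plastome = Plastome("p", "ATGACGTAA", genes=[GeneModel("g", "+", 1, 9)])
    change = annotate_site(_site_for(plastome, 5, "T"), plastome)
    assert change.klass == "nonsynonymous"
    assert (change.aa_before, change.aa_after) == ("T", "M")


def test_annotate_exhaustive_against_biopython_translation():
    """All 64 codons x 3 positions x 3 alternative bases match an independent
    translation oracle (Biopython, plastid/bacterial code)."""
    for codon in map("".join, itertools.product(RNA, repeat=3)):
        dna = "".join(_DNA[b] for b in codon) + "TAA"
        plastome = Plastome("p", dna, genes=[GeneModel("g", "+", 1, 6)])
        for pos in (1, 2, 3):
            for alt in RNA:
                if alt == codon[pos - 1]:
                    continue
                change = annotate_site(_site_for(plastome, pos, _DNA[alt]), plastome)
                after = codon[: pos - 1] + alt + codon[pos:]
                aa_b = str(Seq(codon).translate(table=11))
                aa_a = str(Seq(after).translate(table=11))
                assert change.codon_before == codon
                assert change.codon_after == after
                assert change.aa_before == aa_b and change.aa_after == aa_a
                if change.klass == "synonymous":
                    assert aa_b == aa_a != STOP
                elif change.klass == "stop_gain":
                    assert aa_a == STOP != aa_b
                elif change.klass == "stop_loss":
                    assert aa_b == STOP != aa_a
                elif change.klass == "start_gain":
                    assert after == "AUG"
                else:
                    assert aa_b != aa_a or aa_b == aa_a == STOP


def test_annotate_minus_strand_gene(toy_plastome):
    # ndhB (minus, 25..36) sense CDS ATG CCA TGG TAA; edit sense C(5) -> U:
    # plus-strand coordinate mirrors to end - nt + 1.
    gene = toy_plastome.gene_by_name("ndhB")
    nt = 5
    pos = gene.end - nt + 1
    change = annotate_site(_site_for(toy_plastome, pos, "A"), toy_plastome)
    assert change.nt_index == 5 and change.codon_pos == 2 and change.aa_index == 2
    assert change.codon_before == "CCA" and change.codon_after == "CUA"
    assert (change.aa_before, change.aa_after) == ("P", "L")


def test_annotate_rejects_non_coding(toy_plastome):
    site = _site_for(toy_plastome, 45, "T")
    with pytest.raises(ValueError, match="not protein-coding"):
        annotate_site(site, toy_plastome)


def test_injected_edits_round_trip_through_annotation(sim42, sim42_sites):
    """Annotating each called site reproduces the codon change implied by the
    injected truth (conversion at the recorded CDS offset)."""
    _, plastome, truth, _, _ = sim42
    by_pos = truth.site_by_position()
    checked = 0
    for site in sim42_sites:
        injected = by_pos[site.position]
        change = annotate_site(site, plastome)
        assert change.gene == injected.gene
        assert change.nt_index == injected.nt_index
        src, alt = injected.conversion.split("-to-")
        assert change.codon_before[change.codon_pos - 1] == src
        assert change.codon_after[change.codon_pos - 1] == alt
        checked += 1
    assert checked == 20


@pytest.mark.parametrize(
    "cb,ca,klass,inconsistent",
    [
        ("AUC", "AUU", "synonymous", False),
        ("GUC", "GUU", "synonymous", False),
        ("UCA", "UCA", "synonymous", True),  # identity row flagged
        ("UCA", "UUU", "nonsynonymous", True),  # two-position change flagged
        ("CAA", "UAA", "stop_gain", False),
    ],
)
def test_classify_fixture_row(cb, ca, klass, inconsistent):
    assert classify_fixture_row(cb, ca) == (klass, inconsistent)


def test_classify_fixture_row_rejects_non_triplets():
    with pytest.raises(ValueError):
        classify_fixture_row("AU", "AUU")


def test_display_rendering():
    assert render_display("UCA", "UUA", "S", "L") == "S(uCa) → L(uUa)"
    assert render_display("CAA", "UAA", "Q", STOP) == "Q(Caa) → stop(Uaa)"


def test_fixture_display_strings_match_printed_convention():
    """Re-rendering each fixture row reproduces the printed change string
    (uppercase edited letter, lowercase context)."""
    df = load_fixture("table2")
    for _, row in df[~df["is_rrna"]].iterrows():
        rendered = render_display(
            row["codon_before"], row["codon_after"],
            row["aa_before_printed"], row["aa_after_printed"],
        )
        aa_b = "stop" if row["aa_before_printed"] == "*" else row["aa_before_printed"]
        aa_a = "stop" if row["aa_after_printed"] == "*" else row["aa_after_printed"]
        assert rendered.startswith(f"{aa_b}(")
        assert f"→ {aa_a}(" in rendered
        # exactly one uppercase (edited) letter inside each codon rendering
        import re

        codons = re.findall(r"\(([a-zA-Z]+)\)", rendered)
        assert len(codons) == 2
        for c in codons:
            assert sum(ch.isupper() for ch in c) == 1


def test_summarize_by_group_and_spectrum_small_cases():
    assert summarize_by_group([]) == {}
    assert summarize_by_group(["ndhB", "ndhF", "rbcL"]) == {
        "NADH oxidoreductase": 2,
        "Rubisco": 1,
    }
    assert summarize_spectrum([("S", "L")]) == {("S", "L"): 1}
    assert summarize_spectrum([("S", "S"), ("S", "L")]) == {
        "synonymous": 1,
        ("S", "L"): 1,
    }
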