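"""Codon-level annotation of editing sites in protein-coding genes.

Each coding-region editing site is placed in its codon (1-based amino-acid
index, nucleotide offset in the spliced CDS, codon position 1–3), the
before/after codons are translated under the plastid genetic code, and the
change is classified: synonymous, nonsynonymous, stop_gain, stop_loss, or
start_gain (an ACG→AUG edit at codon 1, a known way editing restores a
canonical translation start).  Display strings follow the site-table
convention "S(uCa) → L(uUa)" with the edited letter uppercase.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

from .calling import EditingSite
from .genome import STOP, GeneModel, Plastome, assign_group, translate_codon

__all__ = [
    "CodonChange",
    "annotate_site",
    "classify_change",
    "classify_fixture_row",
    "render_display",
    "summarize_by_group",
    "summarize_spectrum",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class CodonChange:
    """Effect of a single-base edit on its codon."""

    gene: str
    aa_index: int
    nt_index: int
    codon_pos: int
    codon_before: str
    codon_after: str
    aa_before: str
    aa_after: str
    klass: str  # synonymous | nonsynonymous | stop_gain | stop_loss | start_gain
    display: str
    inconsistent: bool = False


def classify_change(
    codon_before: str,
    codon_after: str,
    aa_index: int | None = None,
    code: Mapping[str, str] | None = None,
) -> tuple[str, str, str]:
    """Classify an RNA codon change; returns (aa_before, aa_after, klass).

    ``start_gain`` is only assigned when ``aa_index == 1`` and the edited
    codon is AUG.  Stop-containing changes never count as synonymous.
    """
    aa_b = translate_codon(codon_before, code)
    aa_a = translate_codon(codon_after, code)
    if aa_index == 1 and codon_after == "AUG" and codon_before != "AUG":
        klass = "start_gain"
    elif aa_a == STOP and aa_b != STOP:
        klass = "stop_gain"
    elif aa_b == STOP and aa_a != STOP:
        klass = "stop_loss"
    elif aa_b == aa_a and aa_b != STOP:
        klass = "synonymous"
    else:
        klass = "nonsynonymous"
    return aa_b, aa_a, klass


def render_display(
    codon_before: str, codon_after: str, aa_before: str, aa_after: str
) -> str:
    """Format "S(uCa) → L(uUa)": lowercase codons, edited letter uppercase."""
    diff = [i for i in range(3) if codon_before[i] != codon_after[i]]
    mark = diff[0] if diff else None

    def fmt(codon: str) -> str:
        return "".join(
            c.upper() if i == mark else c.lower() for i, c in enumerate(codon)
        )

    aa_b = "stop" if aa_before == STOP else aa_before
    aa_a = "stop" if aa_after == STOP else aa_after
    return f"{aa_b}({fmt(codon_before)}) → {aa_a}({fmt(codon_after)})"


def annotate_site(
    site: EditingSite,
    plastome: Plastome,
    code: Mapping[str, str] | None = None,
) -> CodonChange:
    """Annotate an editing site that falls inside a protein-coding gene."""
    if site.gene is None:
        raise ValueError(f"site at {site.position} lies outside any gene")
    gene: GeneModel = plastome.gene_by_name(site.gene)
    if gene.kind != "protein":
        raise ValueError(f"gene {gene.name} is not protein-coding")
    if gene.length % 3 != 0:
        raise ValueError(f"gene {gene.name} length {gene.length} not divisible by 3")

    if gene.strand == "+":
        nt_index = site.position - gene.start + 1
        edited_sense = site.edited_base_plus
    else:
        nt_index = gene.end - site.position + 1
        edited_sense = _COMPLEMENT[site.edited_base_plus]

    aa_index = (nt_index - 1) // 3 + 1
    codon_pos = (nt_index - 1) % 3 + 1

    cds = plastome.gene_sequence(gene)
    codon_dna = cds[3 * (aa_index - 1) : 3 * aa_index]
    codon_before = codon_dna.replace("T", "U")
    edited_rna = edited_sense.replace("T", "U")
    codon_after = (
        codon_before[: codon_pos - 1] + edited_rna + codon_before[codon_pos:]
    )
    aa_b, aa_a, klass = classify_change(codon_before, codon_after, aa_index, code)
    return CodonChange(
        gene=gene.name,
        aa_index=aa_index,
        nt_index=nt_index,
        codon_pos=codon_pos,
        codon_before=codon_before,
        codon_after=codon_after,
        aa_before=aa_b,
        aa_after=aa_a,
        klass=klass,
        display=render_display(codon_before, codon_after, aa_b, aa_a),
    )


def classify_fixture_row(
    codon_before: str, codon_after: str, code: Mapping[str, str] | None = None
) -> tuple[str, bool]:
    """Classify a transcribed table row from its printed codons.

    Returns ``(klass, inconsistent)``: rows whose printed codons differ at
    more than one position (or not at all) are classified from the printed
    codons anyway and flagged inconsistent.
    """
    cb, ca = codon_before.upper(), codon_after.upper()
    if len(cb) != 3 or len(ca) != 3:
        raise ValueError("codons must be RNA triplets")
    _, _, klass = classify_change(cb, ca, None, code)
    n_diff = sum(a != b for a, b in zip(cb, ca))
    return klass, n_diff != 1


def summarize_by_group(rows: Iterable) -> dict[str, int]:
    """Count editing sites per gene group.

    Accepts anything with a ``gene`` attribute, mappings with a ``"gene"``
    key, or bare gene-name strings.
    """
    counts: Counter[str] = Counter()
    for row in rows:
        if isinstance(row, str):
            name = row
        elif hasattr(row, "gene"):
            name = row.gene
        else:
            name = row["gene"]
        counts[assign_group(name)] += 1
    return dict(counts)


def summarize_spectrum(
    changes: Iterable[CodonChange | tuple[str, str]],
) -> dict[tuple[str, str] | str, int]:
    """Count amino-acid transitions; synonymous changes are pooled.

    Nonsynonymous (and stop/start-affecting) changes are keyed by
    ``(aa_before, aa_after)``; synonymous changes count under the single key
    ``"synonymous"``.
    """
    counts: Counter = Counter()
    for ch in changes:
        if isinstance(ch, tuple):
            aa_b, aa_a = ch
            synonymous = aa_b == aa_a and aa_b != STOP
        else:
            aa_b, aa_a = ch.aa_before, ch.aa_after
            synonymous = ch.klass == "synonymous"
        if synonymous:
            counts["synonymous"] += 1
        else:
            counts[(aa_b, aa_a)] += 1
    return dict(counts)
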