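"""Synthetic plastomes and RNA reads with ground truth.

The generator emulates the structure of a real plastid genome at reduced
scale: a quadripartite sequence (LSC + IRA + SSC + IRB, with IRB the
reverse complement of IRA), intronless protein genes (ATG ... stop, no
internal stop) placed without overlap on both strands of the single-copy
regions, heterogeneous per-gene expression, RNA editing injected at chosen
coding positions with per-read Bernoulli conversion at a target fraction,
and fixed-length reads (default 76 bp) with independent substitution
errors.  Everything is deterministic under the configuration seed, and a
truth table records what was injected so caller output can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .calling import EditingSite
from .genome import (
    GeneModel,
    Plastome,
    quadripartite_length,
    reverse_complement,
)

__all__ = [
    "SimulationConfig",
    "InjectedSite",
    "TruthRead",
    "TruthTable",
    "make_plastome",
    "simulate_reads",
    "write_sam",
    "write_truth_tsv",
    "truth_compare",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Defaults are the package's reference scenario: a reduced quadripartite
    plastome, 20 injected C-to-U/U-to-C editing sites at conversion
    fractions of at least 0.15, 76 bp reads with a 0.1% per-base
    substitution error rate, and read depth chosen so every injected site
    sees comfortably more than 200-fold coverage.
    """

    seed: int = 0
    lsc_len: int = 18000
    ssc_len: int = 6000
    ir_len: int = 3000
    n_genes: int = 24
    strand_fraction_minus: float = 0.5
    gene_codon_range: tuple[int, int] = (100, 300)  # codons incl. start/stop
    intergenic_gap_range: tuple[int, int] = (60, 200)
    expression_weights: dict[str, float] | None = None  # default: log-uniform
    editing_sites: Sequence[tuple[str, int, str, float]] | None = None
    n_editing_sites: int = 20
    editing_fraction_range: tuple[float, float] = (0.15, 0.9)
    editing_conversions: tuple[str, ...] = ("C-to-U", "U-to-C")
    read_length: int = 76
    n_reads: int | None = None  # None: auto-scale for target site coverage
    target_site_coverage: int = 300
    error_rate: float = 0.001


@dataclass(frozen=True)
class InjectedSite:
    """An injected editing site, in both CDS and plus-strand coordinates."""

    gene: str
    nt_index: int  # 1-based position in the gene-strand CDS
    conversion: str  # gene-strand content, e.g. "C-to-U"
    fraction: float
    position_plus: int
    ref_plus: str
    alt_plus: str


@dataclass(frozen=True)
class TruthRead:
    name: str
    gene: str
    strand: str
    start: int  # 1-based plus-strand alignment start
    seq_plus: str  # aligned sequence in plus-strand orientation
    n_errors: int


@dataclass
class TruthTable:
    gene_weights: dict[str, float] = field(default_factory=dict)
    editing_sites: list[InjectedSite] = field(default_factory=list)
    reads: list[TruthRead] = field(default_factory=list)

    def site_by_position(self) -> dict[int, InjectedSite]:
        return {s.position_plus: s for s in self.editing_sites}


def _random_gene_sequence(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons − 2) random non-stop codons + TAA."""
    body = rng.choice(len(_NON_STOP_CODONS), size=n_codons - 2)
    return "ATG" + "".join(_NON_STOP_CODONS[i] for i in body) + "TAA"


def _dna(base_rna: str) -> str:
    return "T" if base_rna == "U" else base_rna


def make_plastome(config: SimulationConfig) -> tuple[Plastome, TruthTable]:
    """Build a random quadripartite plastome with placed genes and truth.

    Genes live in the single-copy regions only, so the IR mirror property
    (IRB = reverse complement of IRA) is exact by construction.
    """
    rng = np.random.default_rng([config.seed, 0])
    lsc, ssc, ir = config.lsc_len, config.ssc_len, config.ir_len
    total = quadripartite_length(lsc, ssc, ir)
    seq = rng.choice(list("ACGT"), size=total)

    regions = [
        ("LSC", 1, lsc),
        ("IRA", lsc + 1, lsc + ir),
        ("SSC", lsc + ir + 1, lsc + ir + ssc),
        ("IRB", lsc + ir + ssc + 1, total),
    ]

    # Place genes left to right within LSC then SSC, separated by random gaps.
    windows = [(1, lsc), (lsc + ir + 1, lsc + ir + ssc)]
    genes: list[GeneModel] = []
    gmin, gmax = config.gene_codon_range
    if 3 * gmin < config.read_length:
        raise ValueError("shortest gene must be at least one read long")
    wi = 0
    cursor = windows[0][0]
    placed = 0
    while placed < config.n_genes:
        n_codons = int(rng.integers(gmin, gmax + 1))
        gap = int(rng.integers(*config.intergenic_gap_range))
        length = 3 * n_codons
        start = cursor + gap
        end = start + length - 1
        if end > windows[wi][1]:
            wi += 1
            if wi >= len(windows):
                raise ValueError(
                    f"cannot fit {config.n_genes} genes into the single-copy regions"
                )
            cursor = windows[wi][0]
            continue
        strand = "-" if rng.random() < config.strand_fraction_minus else "+"
        gene_seq = _random_gene_sequence(rng, n_codons)
        insert = gene_seq if strand == "+" else reverse_complement(gene_seq)
        seq[start - 1 : end] = list(insert)
        genes.append(
            GeneModel(name=f"g{placed + 1:02d}", strand=strand, start=start, end=end)
        )
        cursor = end + 1
        placed += 1

    # Mirror the inverted repeat.
    ira = "".join(seq[lsc : lsc + ir])
    seq[lsc + ir + ssc : total] = list(reverse_complement(ira))

    plastome = Plastome(
        seq_id=f"synthetic_plastome_seed{config.seed}",
        sequence="".join(seq),
        regions=regions,
        genes=genes,
    )

    truth = TruthTable(gene_weights=_gene_weights(plastome, config, rng))
    truth.editing_sites = _choose_editing_sites(plastome, config, rng)
    return plastome, truth


def _gene_weights(
    plastome: Plastome, config: SimulationConfig, rng: np.random.Generator
) -> dict[str, float]:
    if config.expression_weights is not None:
        return dict(config.expression_weights)
    # Log-uniform over one decade: heterogeneous but no gene starves.
    w = 10 ** rng.uniform(-0.5, 0.5, size=len(plastome.genes))
    return {g.name: float(x) for g, x in zip(plastome.genes, w)}


def _choose_editing_sites(
    plastome: Plastome, config: SimulationConfig, rng: np.random.Generator
) -> list[InjectedSite]:
    specs = config.editing_sites
    sites: list[InjectedSite] = []
    if specs is None:
        specs = []
        if config.n_editing_sites > 0:
            if not plastome.genes:
                raise ValueError("cannot inject editing sites without genes")
            lo, hi = config.editing_fraction_range
            order = list(range(len(plastome.genes)))
            for k in range(config.n_editing_sites):
                gene = plastome.genes[order[k % len(order)]]
                conversion = config.editing_conversions[
                    int(rng.integers(len(config.editing_conversions)))
                ]
                src = _dna(conversion.split("-to-")[0])
                cds = plastome.gene_sequence(gene)
                # Interior positions only (full single-read coverage zone),
                # and outside the start/stop codons.
                zone_lo = max(config.read_length, 4)
                zone_hi = min(gene.length - config.read_length, gene.length - 3)
                candidates = [
                    i + 1
                    for i in range(zone_lo - 1, zone_hi)
                    if cds[i] == src
                ]
                if not candidates:
                    raise ValueError(
                        f"gene {gene.name} has no {src} in its interior zone"
                    )
                nt = int(rng.choice(candidates))
                fraction = float(rng.uniform(lo, hi))
                specs.append((gene.name, nt, conversion, fraction))
    for gene_name, nt, conversion, fraction in specs:
        gene = plastome.gene_by_name(gene_name)
        if not 0 < fraction <= 1:
            raise ValueError("target fraction must lie in (0, 1]")
        if not 1 <= nt <= gene.length:
            raise ValueError(f"editing position {nt} outside CDS of {gene_name}")
        src_rna, alt_rna = conversion.split("-to-")
        src, alt = _dna(src_rna), _dna(alt_rna)
        cds = plastome.gene_sequence(gene)
        if cds[nt - 1] != src:
            raise ValueError(
                f"{gene_name} CDS has {cds[nt - 1]} at {nt}, cannot inject {conversion}"
            )
        if gene.strand == "+":
            pos = gene.start + nt - 1
            ref_plus, alt_plus = src, alt
        else:
            pos = gene.end - nt + 1
            ref_plus, alt_plus = _COMPLEMENT[src], _COMPLEMENT[alt]
        sites.append(
            InjectedSite(
                gene=gene_name,
                nt_index=nt,
                conversion=conversion,
                fraction=fraction,
                position_plus=pos,
                ref_plus=ref_plus,
                alt_plus=alt_plus,
            )
        )
    return sites


def _auto_n_reads(plastome: Plastome, truth: TruthTable, config: SimulationConfig) -> int:
    """Smallest read count giving the target expected coverage at every site."""
    weights = truth.gene_weights
    total_w = sum(weights.values())
    rl = config.read_length
    needed = 1
    edited = {s.gene for s in truth.editing_sites} or {
        g.name for g in plastome.genes
    }
    for name in edited:
        gene = plastome.gene_by_name(name)
        n_offsets = gene.length - rl + 1
        p_cover = (weights[name] / total_w) * min(rl, n_offsets) / n_offsets
        needed = max(needed, math.ceil(config.target_site_coverage / p_cover))
    return needed


def simulate_reads(
    plastome: Plastome,
    truth: TruthTable,
    config: SimulationConfig,
    sam_path: str | Path | None = None,
) -> tuple[list[TruthRead], TruthTable]:
    """Draw reads from genes, inject editing and errors, record truth.

    Reads are sampled from spliced gene sequences only (no intergenic
    transcription), with genes chosen proportionally to their expression
    weights and start offsets uniform within the gene.  At each injected
    site, a covering read carries the edited base with probability equal to
    the site's target fraction, independently per read.  Substitution
    errors hit each base independently at ``error_rate``.  Optionally
    writes a SAM file of the alignments.
    """
    rng = np.random.default_rng([config.seed, 1])
    genes = plastome.genes
    if not genes:
        raise ValueError("plastome has no genes to transcribe")
    rl = config.read_length
    for g in genes:
        if rl > g.length:
            raise ValueError(f"read length {rl} exceeds gene {g.name} length {g.length}")
    weights = np.array([truth.gene_weights[g.name] for g in genes], dtype=float)
    probs = weights / weights.sum()
    n_reads = config.n_reads
    if n_reads is None:
        n_reads = _auto_n_reads(plastome, truth, config)

    cds_by_gene = {g.name: plastome.gene_sequence(g) for g in genes}
    sites_by_gene: dict[str, list[InjectedSite]] = {}
    for s in truth.editing_sites:
        sites_by_gene.setdefault(s.gene, []).append(s)

    gene_idx = rng.choice(len(genes), size=n_reads, p=probs)
    reads: list[TruthRead] = []
    for r, gi in enumerate(gene_idx):
        gene = genes[gi]
        cds = cds_by_gene[gene.name]
        off = int(rng.integers(0, gene.length - rl + 1))
        bases = list(cds[off : off + rl])
        for site in sites_by_gene.get(gene.name, ()):
            j = site.nt_index - off - 1
            if 0 <= j < rl and rng.random() < site.fraction:
                bases[j] = _dna(site.conversion.split("-to-")[1])
        n_err = 0
        if config.error_rate > 0:
            err = np.flatnonzero(rng.random(rl) < config.error_rate)
            for j in err:
                choices = [b for b in "ACGT" if b != bases[j]]
                bases[j] = choices[int(rng.integers(3))]
            n_err = len(err)
        seq_gene_strand = "".join(bases)
        if gene.strand == "+":
            start = gene.start + off
            seq_plus = seq_gene_strand
        else:
            start = gene.end - (off + rl) + 1
            seq_plus = reverse_complement(seq_gene_strand)
        reads.append(
            TruthRead(
                name=f"read{r:07d}",
                gene=gene.name,
                strand=gene.strand,
                start=start,
                seq_plus=seq_plus,
                n_errors=n_err,
            )
        )
    truth.reads = reads
    if sam_path is not None:
        write_sam(reads, plastome, sam_path)
    return reads, truth


def write_sam(reads: Iterable[TruthRead], plastome: Plastome, path: str | Path) -> None:
    """Write truth alignments as minimal plain-text SAM (all-match CIGAR)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{plastome.seq_id}\tLN:{len(plastome)}\n")
        for r in reads:
            flag = 16 if r.strand == "-" else 0
            seq = r.seq_plus
            fh.write(
                f"{r.name}\t{flag}\t{plastome.seq_id}\t{r.start}\t60\t"
                f"{len(seq)}M\t*\t0\t0\t{seq}\t{'I' * len(seq)}\n"
            )


def write_truth_tsv(truth: TruthTable, sites_path: str | Path, reads_path: str | Path | None = None) -> None:
    with open(sites_path, "w") as fh:
        fh.write("gene\tnt_index\tconversion\tfraction\tposition_plus\tref_plus\talt_plus\n")
        for s in truth.editing_sites:
            fh.write(
                f"{s.gene}\t{s.nt_index}\t{s.conversion}\t{s.fraction:.4f}\t"
                f"{s.position_plus}\t{s.ref_plus}\t{s.alt_plus}\n"
            )
    if reads_path is not None:
        with open(reads_path, "w") as fh:
            fh.write("name\tgene\tstrand\tstart\tlength\tn_errors\n")
            for r in truth.reads:
                fh.write(
                    f"{r.name}\t{r.gene}\t{r.strand}\t{r.start}\t"
                    f"{len(r.seq_plus)}\t{r.n_errors}\n"
                )


def run_recovery(
    seed: int = 42,
    min_coverage: int = 100,
    config: SimulationConfig | None = None,
) -> dict:
    """Full-pipeline recovery experiment on one synthetic dataset.

    Simulates the reference scenario (20 injected sites at fractions of at
    least 0.15, ≥200× coverage, 0.1% error), calls sites from the pileup
    with a coverage floor matched to the scenario's depth guarantee, and
    scores against truth.
    """
    from .calling import call_sites
    from .pileup import pileup_from_truth

    if config is None:
        config = SimulationConfig(seed=seed)
    plastome, truth = make_plastome(config)
    reads, truth = simulate_reads(plastome, truth, config)
    pileups = pileup_from_truth(reads, plastome)
    sites = call_sites(pileups, plastome, min_coverage=min_coverage)
    sensitivity, false_positives = truth_compare(sites, truth)
    return {
        "sensitivity": sensitivity,
        "false_positives": false_positives,
        "n_called": len(sites),
        "n_injected": len(truth.editing_sites),
        "n_reads": len(reads),
        "min_site_coverage": min(
            pileups[s.position_plus].coverage for s in truth.editing_sites
        )
        if truth.editing_sites
        else 0,
    }


def truth_compare(
    called_sites: Iterable[EditingSite],
    truth: TruthTable,
    threshold: float = 0.05,
) -> tuple[float, int]:
    """Score called sites against the injected truth.

    Sensitivity counts injected sites with target fraction strictly above
    the calling threshold (others could not legitimately be called); false
    positives are called positions never injected.
    """
    called_positions = {s.position for s in called_sites}
    expected = [s for s in truth.editing_sites if s.fraction > threshold]
    injected_positions = {s.position_plus for s in truth.editing_sites}
    if expected:
        hit = sum(1 for s in expected if s.position_plus in called_positions)
        sensitivity = hit / len(expected)
    else:
        sensitivity = 1.0
    false_positives = len(called_positions - injected_positions)
    return sensitivity, false_positives
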