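"""Plastome data model: sequence, quadripartite regions, gene models, genetic code.

The chloroplast genome (plastome) of most land plants is quadripartite: a
large single-copy region (LSC), a small single-copy region (SSC) and two
inverted repeats (IRA/IRB) whose sequences are reverse complements of each
other.  Genes are modelled as intronless spans on the plus strand with a
strand flag; minus-strand coding sequence is the reverse complement of the
plus-strand slice.  Translation uses the bacterial/plastid genetic code
(NCBI translation table 11).
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "STOP",
    "GENETIC_CODE",
    "GeneModel",
    "Plastome",
    "assign_group",
    "translate_codon",
    "quadripartite_length",
    "read_plastome",
    "write_plastome",
    "reverse_complement",
    "has_internal_stop",
]

STOP = "*"

REGION_NAMES = ("LSC", "IRA", "SSC", "IRB")

_TABLE11 = CodonTable.unambiguous_rna_by_id[11]

#: RNA codon -> one-letter amino acid, stop codons mapping to ``STOP``.
GENETIC_CODE: dict[str, str] = dict(_TABLE11.forward_table)
GENETIC_CODE.update({c: STOP for c in _TABLE11.stop_codons})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a plus-strand DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


# Gene-group prefix rules.  Order matters only for readability; prefixes are
# mutually exclusive.  Anything unmatched falls back to "miscellaneous"
# (matK, cemA, ccsA, accD, clpP, infA, trn*, ...).
_GROUP_PREFIXES = (
    (("psa", "psb"), "Photosystem I and II"),
    (("rpo",), "RNA polymerase"),
    (("ndh",), "NADH oxidoreductase"),
    (("rps", "rpl"), "ribosomal proteins"),
    (("atp",), "ATP synthase"),
    (("pet",), "cytochrome b6/f"),
    (("rbcL",), "Rubisco"),
    (("rrn",), "rRNAs"),
    (("ycf",), "hypothetical proteins"),
)

MISC_GROUP = "miscellaneous"

GENE_GROUPS = tuple(g for _, g in _GROUP_PREFIXES) + (MISC_GROUP,)


def assign_group(gene_name: str) -> str:
    """Assign a gene to its functional group by name prefix.

    Unrecognised names (matK, cemA, accD, clpP, infA, tRNAs, ...) map to
    ``"miscellaneous"``.
    """
    if not gene_name:
        raise ValueError("gene name must be non-empty")
    for prefixes, group in _GROUP_PREFIXES:
        if any(gene_name.startswith(p) for p in prefixes):
            return group
    return MISC_GROUP


def translate_codon(codon_rna: str, code: dict[str, str] | None = None) -> str:
    """Translate a 3-letter RNA codon to a one-letter amino acid or ``"*"``.

    Raises ``ValueError`` for non-triplets or letters outside {A,C,G,U}.
    """
    code = GENETIC_CODE if code is None else code
    codon = codon_rna.upper()
    if len(codon) != 3 or any(b not in "ACGU" for b in codon):
        raise ValueError(f"not an RNA codon: {codon_rna!r}")
    return code[codon]


def quadripartite_length(lsc_len: int, ssc_len: int, ir_len: int) -> int:
    """Total plastome length LSC + SSC + 2×IR for a quadripartite genome."""
    for name, v in (("lsc_len", lsc_len), ("ssc_len", ssc_len), ("ir_len", ir_len)):
        if int(v) != v or v <= 0:
            raise ValueError(f"{name} must be a positive integer, got {v!r}")
    return int(lsc_len) + int(ssc_len) + 2 * int(ir_len)


@dataclass
class GeneModel:
    """A gene span in 1-based inclusive plus-strand coordinates."""

    name: str
    strand: str  # '+' or '-'
    start: int
    end: int
    kind: str = "protein"  # protein | rRNA | tRNA
    group: str = ""
    pseudo: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"unknown strand symbol {self.strand!r} for {self.name}")
        if self.start > self.end:
            raise ValueError(f"gene {self.name}: start > end")
        if not self.group:
            self.group = assign_group(self.name)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class Plastome:
    """Single-record plastid genome with optional quadripartite regions."""

    seq_id: str
    sequence: str
    topology: str = "circular"
    regions: list[tuple[str, int, int]] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if re.search(r"[^ACGTN]", self.sequence):
            raise ValueError("plastome sequence must be DNA over {A,C,G,T,N}")
        for g in self.genes:
            if g.end > len(self.sequence):
                raise ValueError(
                    f"gene {g.name} (..{g.end}) outside sequence bounds "
                    f"(length {len(self.sequence)})"
                )
        self.genes.sort(key=lambda g: (g.start, g.end))
        self._starts = [g.start for g in self.genes]
        if self.regions:
            self.validate_regions()

    def __len__(self) -> int:
        return len(self.sequence)

    def validate_regions(self) -> None:
        """Check that named regions are sane; all four must tile the genome."""
        byname = {name: (s, e) for name, s, e in self.regions}
        for name, s, e in self.regions:
            if not (1 <= s <= e <= len(self.sequence)):
                raise ValueError(f"region {name} out of bounds")
        if set(byname) == set(REGION_NAMES):
            spans = sorted((s, e) for s, e in byname.values())
            cursor = 1
            for s, e in spans:
                if s != cursor:
                    raise ValueError("quadripartite regions must tile the sequence")
                cursor = e + 1
            if cursor != len(self.sequence) + 1:
                raise ValueError("quadripartite regions must tile the sequence")

    def region_of(self, position: int) -> str | None:
        for name, s, e in self.regions:
            if s <= position <= e:
                return name
        return None

    def gene_at(self, position: int) -> GeneModel | None:
        """Gene covering a 1-based position, or ``None`` (IGS).

        Genes are assumed non-overlapping; the left-most covering gene wins
        if they do overlap.
        """
        i = bisect_right(self._starts, position)
        for g in self.genes[max(0, i - 3) : i][::-1]:
            if g.contains(position):
                return g
        return None

    def gene_by_name(self, name: str) -> GeneModel:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def gene_sequence(self, gene: GeneModel | str) -> str:
        """Gene-strand (sense) DNA sequence of a gene."""
        if isinstance(gene, str):
            gene = self.gene_by_name(gene)
        s = self.sequence[gene.start - 1 : gene.end]
        return s if gene.strand == "+" else reverse_complement(s)


def has_internal_stop(cds_dna: str, code: dict[str, str] | None = None) -> bool:
    """True if any sense codon before the last encodes a stop.

    Used as the generic pseudogene test (covers frameshift-type defects such
    as homopolymer length changes that push stops into frame).
    """
    for i in range(0, len(cds_dna) - 3, 3):
        codon = cds_dna[i : i + 3].replace("T", "U")
        if len(codon) == 3 and GENETIC_CODE.get(codon) == STOP:
            return True
    return False


# ---------------------------------------------------------------------------
# FASTA + GFF3 io

_KIND_BY_TYPE = {
    "gene": "protein",
    "CDS": "protein",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
}


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_plastome(fasta_path: str | Path, gff3_path: str | Path) -> Plastome:
    """Load a single-record FASTA plus GFF3 gene/region annotations.

    Gene features (types gene/rRNA/tRNA) need a ``Name`` or ``ID`` attribute;
    an optional ``pseudo=true`` attribute marks pseudogenes and
    ``gene_biotype``/``kind`` may override the feature-type-derived kind.
    ``region`` features named LSC/SSC/IRA/IRB populate the quadripartite map.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, got {len(records)}")
    rec = records[0]
    sequence = str(rec.seq).upper()

    genes: list[GeneModel] = []
    regions: list[tuple[str, int, int]] = []
    with open(gff3_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            _seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            start_i, end_i = int(start), int(end)
            a = _parse_gff3_attributes(attrs)
            if ftype == "region":
                name = a.get("Name", a.get("ID", ""))
                if name in REGION_NAMES:
                    regions.append((name, start_i, end_i))
                continue
            if ftype not in _KIND_BY_TYPE:
                continue
            name = a.get("Name") or a.get("ID")
            if not name:
                raise ValueError(f"gene feature without Name/ID: {line!r}")
            if end_i > len(sequence):
                raise ValueError(
                    f"gene {name} end {end_i} exceeds sequence length {len(sequence)}"
                )
            kind = a.get("kind", a.get("gene_biotype", _KIND_BY_TYPE[ftype]))
            genes.append(
                GeneModel(
                    name=name,
                    strand=strand,
                    start=start_i,
                    end=end_i,
                    kind=kind,
                    pseudo=a.get("pseudo", "").lower() == "true",
                )
            )
    return Plastome(seq_id=rec.id, sequence=sequence, regions=regions, genes=genes)


def write_plastome(
    plastome: Plastome, fasta_path: str | Path, gff3_path: str | Path
) -> None:
    """Write the FASTA record and a GFF3 with region + gene features."""
    with open(fasta_path, "w") as fh:
        fh.write(f">{plastome.seq_id}\n")
        seq = plastome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    type_by_kind = {"protein": "gene", "rRNA": "rRNA", "tRNA": "tRNA"}
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {plastome.seq_id} 1 {len(plastome)}\n")
        for name, s, e in plastome.regions:
            fh.write(
                f"{plastome.seq_id}\tplastedit\tregion\t{s}\t{e}\t.\t+\t.\tName={name}\n"
            )
        for g in plastome.genes:
            attrs = f"ID={g.name};Name={g.name};kind={g.kind}"
            if g.pseudo:
                attrs += ";pseudo=true"
            fh.write(
                f"{plastome.seq_id}\tplastedit\t{type_by_kind.get(g.kind, 'gene')}\t"
                f"{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
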