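"""Intergenic-spacer (IGS) extraction and pairwise percent identity.

IGS regions — the sequence between consecutive annotated genes along the
plus strand — evolve faster than coding sequence; spacers whose identity
between two plastomes falls below 95% are flagged as mutation hotspots.
Identity is computed from a global (Needleman–Wunsch) alignment with
match +1 / mismatch −1 / gap −2, counting gap columns in the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio.Align import PairwiseAligner

from .genome import Plastome

__all__ = [
    "IGSRecord",
    "HOTSPOT_IDENTITY",
    "extract_igs",
    "alignment_score",
    "global_alignment_stats",
    "percent_identity",
    "compare_igs",
    "hotspot_report",
    "write_igs_tsv",
]

HOTSPOT_IDENTITY = 95.0


@dataclass(frozen=True)
class IGSRecord:
    name: str  # "upstreamGene-downstreamGene" along the plus strand
    seq_a: str
    seq_b: str
    identity_pct: float

    @property
    def hotspot(self) -> bool:
        return self.identity_pct < HOTSPOT_IDENTITY


def extract_igs(plastome: Plastome) -> list[tuple[str, str]]:
    """Spacer sequences between consecutive genes (gaps of >= 1 bp).

    Genes of every kind (including tRNAs) delimit spacers.  Overlapping or
    abutting gene pairs yield nothing; a gene nested inside another never
    opens a spacer.
    """
    out: list[tuple[str, str]] = []
    genes = plastome.genes  # sorted by start
    if not genes:
        return out
    prev = genes[0]
    prev_end = prev.end
    for g in genes[1:]:
        if g.start > prev_end + 1:
            seq = plastome.sequence[prev_end : g.start - 1]
            out.append((f"{prev.name}-{g.name}", seq))
        if g.end > prev_end:
            prev, prev_end = g, g.end
    return out


def _aligner(match: float, mismatch: float, gap: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def alignment_score(
    seq_a: str, seq_b: str, match: float = 1, mismatch: float = -1, gap: float = -2
) -> float:
    """Optimal global alignment score (Biopython PairwiseAligner).

    Kept as an independent cross-check for :func:`global_alignment_stats`.
    """
    return _aligner(match, mismatch, gap).score(seq_a.upper(), seq_b.upper())


def global_alignment_stats(
    seq_a: str, seq_b: str, match: float = 1, mismatch: float = -1, gap: float = -2
) -> tuple[float, int, int]:
    """Needleman–Wunsch alignment summary: (score, identities, columns).

    Among all optimal-score alignments the one with the most identical
    columns is chosen, and among those the shortest.  This makes the
    identity canonical: co-optimal alignments can disagree on identity
    count, and fixing the tie-break lexicographically keeps the result
    invariant under sequence swap and under joint reverse complement.
    Quadratic time/space; intended for spacer-scale sequences.
    """
    a, b = seq_a.upper(), seq_b.upper()
    m, n = len(a), len(b)
    # primary: optimal score
    score = [[0.0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        score[i][0] = i * gap
    for j in range(1, n + 1):
        score[0][j] = j * gap
    for i in range(1, m + 1):
        ai = a[i - 1]
        row, prev = score[i], score[i - 1]
        for j in range(1, n + 1):
            sub = match if ai == b[j - 1] else mismatch
            row[j] = max(prev[j - 1] + sub, prev[j] + gap, row[j - 1] + gap)
    # secondary: (identities, -columns) maximized over optimal paths
    tie = [[(0, 0)] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        tie[i][0] = (0, -i)
    for j in range(1, n + 1):
        tie[0][j] = (0, -j)
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            target = score[i][j]
            same = ai == b[j - 1]
            sub = match if same else mismatch
            best = None
            if score[i - 1][j - 1] + sub == target:
                ident, ncol = tie[i - 1][j - 1]
                best = (ident + same, ncol - 1)
            if score[i - 1][j] + gap == target:
                ident, ncol = tie[i - 1][j]
                cand = (ident, ncol - 1)
                best = cand if best is None else max(best, cand)
            if score[i][j - 1] + gap == target:
                ident, ncol = tie[i][j - 1]
                cand = (ident, ncol - 1)
                best = cand if best is None else max(best, cand)
            tie[i][j] = best
    identities, neg_columns = tie[m][n]
    return score[m][n], int(identities), -neg_columns


def percent_identity(
    seq_a: str, seq_b: str, match: float = 1, mismatch: float = -1, gap: float = -2
) -> float:
    """Percent identity over a global end-to-end alignment.

    Identity = 100 × identical columns / total alignment columns; columns
    containing a gap count in the denominator.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    _, identities, columns = global_alignment_stats(seq_a, seq_b, match, mismatch, gap)
    return 100.0 * identities / columns


def compare_igs(plastome_a: Plastome, plastome_b: Plastome) -> list[IGSRecord]:
    """Pairwise identity of spacers shared (by name) between two plastomes."""
    igs_a = dict(extract_igs(plastome_a))
    igs_b = dict(extract_igs(plastome_b))
    records = []
    for name, seq_a in igs_a.items():
        seq_b = igs_b.get(name)
        if seq_b is None or not seq_a or not seq_b:
            continue
        records.append(
            IGSRecord(
                name=name,
                seq_a=seq_a,
                seq_b=seq_b,
                identity_pct=percent_identity(seq_a, seq_b),
            )
        )
    return records


def hotspot_report(records: Iterable[IGSRecord]) -> list[IGSRecord]:
    """Spacers with identity < 95%, most divergent first."""
    return sorted(
        (r for r in records if r.hotspot), key=lambda r: (r.identity_pct, r.name)
    )


def write_igs_tsv(records: Iterable[IGSRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("igs\tlen_a\tlen_b\tidentity_pct\thotspot\n")
        for r in records:
            fh.write(
                f"{r.name}\t{len(r.seq_a)}\t{len(r.seq_b)}\t"
                f"{r.identity_pct:.2f}\t{int(r.hotspot)}\n"
            )
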