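"""Per-position base counts (pileups) from RNA-read alignments.

Counts are always recorded in plus-strand base space: a read mapped to the
minus strand contributes its already plus-strand-oriented aligned bases.
Two input paths exist with the same contract: a SAM path (with the mismatch
filter used for real alignments, mismatch ≤ 2 by default) and a fast truth
path for simulator alignments, which are indel-free by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pysam

from .genome import Plastome

__all__ = [
    "SitePileup",
    "pileup_from_sam",
    "pileup_from_truth",
    "mean_coverage",
    "mapped_fraction",
    "write_pileup_tsv",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class SitePileup:
    """Base counts at one 1-based reference position (Ns/deletions excluded).

    ``coverage`` defaults to the sum of the counts, which is the invariant
    for pileups built here; an explicit value may be supplied when working
    from published per-site tables whose printed coverage includes reads
    not broken out by base.
    """

    position: int
    counts: dict[str, int]
    coverage: int | None = None

    def __post_init__(self) -> None:
        if self.coverage is None:
            object.__setattr__(self, "coverage", sum(self.counts.values()))
        if self.coverage < 0 or any(c < 0 for c in self.counts.values()):
            raise ValueError("counts and coverage must be non-negative")


def _matrix_to_map(matrix: np.ndarray) -> dict[int, SitePileup]:
    out: dict[int, SitePileup] = {}
    covered = np.flatnonzero(matrix.sum(axis=0))
    for col in covered:
        counts = {b: int(matrix[i, col]) for b, i in _BASE_INDEX.items()}
        out[int(col) + 1] = SitePileup(position=int(col) + 1, counts=counts)
    return out


def pileup_from_truth(
    alignments: Iterable, plastome: Plastome
) -> dict[int, SitePileup]:
    """Pileup from simulator truth alignments (1-based start, plus-strand seq).

    Each alignment needs ``start`` and ``seq_plus`` attributes (or is a
    ``(start, seq_plus)`` tuple); no filtering is applied.
    """
    L = len(plastome)
    matrix = np.zeros((4, L), dtype=np.int64)
    for aln in alignments:
        if isinstance(aln, tuple):
            start, seq = aln[0], aln[1]
        else:
            start, seq = aln.start, aln.seq_plus
        end = start + len(seq) - 1
        if start < 1 or end > L:
            raise ValueError(f"alignment {start}..{end} overruns reference of length {L}")
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        pos = np.arange(start - 1, end)
        for b, i in _BASE_INDEX.items():
            sel = codes == ord(b)
            if sel.any():
                np.add.at(matrix[i], pos[sel], 1)
    return _matrix_to_map(matrix)


def pileup_from_sam(
    sam_path: str | Path,
    plastome: Plastome,
    min_base_quality: int = 0,
    max_mismatches: int | None = 2,
) -> dict[int, SitePileup]:
    """Pileup from a SAM file, discarding reads with too many mismatches.

    Unmapped, secondary and supplementary records are skipped.  Inserted
    bases are not counted anywhere; deleted reference positions receive no
    count.  A read is discarded entirely when its aligned-base mismatch count
    against the reference exceeds ``max_mismatches`` (pass ``None`` to keep
    all reads).  Bases below ``min_base_quality`` are excluded from counting
    (quality filtering defaults to off; upstream trimming is assumed).
    """
    L = len(plastome)
    ref = plastome.sequence
    matrix = np.zeros((4, L), dtype=np.int64)
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for idx, rec in enumerate(sam):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.reference_name != plastome.seq_id:
                raise ValueError(
                    f"SAM reference {rec.reference_name!r} does not match "
                    f"plastome {plastome.seq_id!r}"
                )
            seq = rec.query_sequence
            if seq is None:
                continue
            quals = rec.query_qualities
            try:
                pairs = rec.get_aligned_pairs(matches_only=True)
            except ValueError as exc:  # pragma: no cover - malformed CIGAR
                raise ValueError(f"malformed CIGAR in record {idx}") from exc
            placed: list[tuple[int, str]] = []
            mismatches = 0
            for qpos, rpos in pairs:
                base = seq[qpos].upper()
                if base not in _BASE_INDEX or rpos >= L:
                    continue
                if base != ref[rpos]:
                    mismatches += 1
                if quals is None or quals[qpos] >= min_base_quality:
                    placed.append((rpos, base))
            if max_mismatches is not None and mismatches > max_mismatches:
                continue
            for rpos, base in placed:
                matrix[_BASE_INDEX[base], rpos] += 1
    return _matrix_to_map(matrix)


def mean_coverage(n_reads: int, read_length: int, genome_length: int) -> float:
    """Fold coverage n_reads × read_length / genome_length, to one decimal."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if n_reads < 0 or read_length <= 0:
        raise ValueError("n_reads must be >= 0 and read_length positive")
    return round(n_reads * read_length / genome_length, 1)


def mapped_fraction(n_mapped: int, n_total: int) -> float:
    """Percentage of reads mapped, to two decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_mapped <= n_total:
        raise ValueError("need 0 <= n_mapped <= n_total")
    return round(100.0 * n_mapped / n_total, 2)


def write_pileup_tsv(pileups: Mapping[int, SitePileup], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tA\tC\tG\tT\tcoverage\n")
        for pos in sorted(pileups):
            p = pileups[pos]
            fh.write(
                f"{pos}\t{p.counts['A']}\t{p.counts['C']}\t{p.counts['G']}\t"
                f"{p.counts['T']}\t{p.coverage}\n"
            )
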