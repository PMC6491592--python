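"""RNA secondary structure by base-pair maximization (Nussinov algorithm).

A deterministic dynamic program maximizes the number of nested base pairs
(Watson–Crick plus, by default, G·U wobble) subject to a minimum hairpin
loop of 3 unpaired bases.  This is a combinatorial stand-in for
thermodynamic folding: adequate for asking whether a single editing event
rewires pairing, not for predicting real minimum-free-energy structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "SecondaryStructure",
    "fold",
    "structure_delta",
    "pairs_to_dot_bracket",
    "dot_bracket_to_pairs",
    "write_vienna",
]

_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_GU = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested set of base pairs over an RNA sequence (1-based indices)."""

    sequence: str
    pairs: frozenset[tuple[int, int]]
    dot_bracket: str

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _can_pair(a: str, b: str, allow_gu: bool) -> bool:
    return (a, b) in _WC or (allow_gu and (a, b) in _GU)


def pairs_to_dot_bracket(pairs, length: int) -> str:
    chars = ["."] * length
    for i, j in pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


def dot_bracket_to_pairs(dot_bracket: str) -> frozenset[tuple[int, int]]:
    stack: list[int] = []
    pairs = set()
    for idx, c in enumerate(dot_bracket, start=1):
        if c == "(":
            stack.append(idx)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.add((stack.pop(), idx))
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return frozenset(pairs)


def fold(sequence: str, min_loop: int = 3, allow_gu: bool = True) -> SecondaryStructure:
    """Maximum-pairing nested structure of an RNA sequence.

    ``min_loop`` is the minimum number of unpaired bases enclosed by a pair
    (a pair (i, j) requires j − i > min_loop).  Traceback is deterministic:
    at each interval the pairing branch is preferred, taking the smallest
    admissible partner.
    """
    seq = sequence.upper().replace("T", "U")
    if not seq or any(b not in "ACGU" for b in seq):
        raise ValueError(f"sequence must be non-empty RNA over A/C/G/U: {sequence!r}")
    n = len(seq)
    # dp[i][j]: max pairs in seq[i..j], 0-based inclusive.
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1][j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if _can_pair(seq[i], seq[k], allow_gu):
                    inner = dp[i + 1][k - 1] if k - i > 1 else 0
                    right = dp[k + 1][j] if k < j else 0
                    cand = 1 + inner + right
                    if cand > best:
                        best = cand
            dp[i][j] = best

    pairs: set[tuple[int, int]] = set()
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        target = dp[i][j]
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            if _can_pair(seq[i], seq[k], allow_gu):
                inner = dp[i + 1][k - 1] if k - i > 1 else 0
                right = dp[k + 1][j] if k < j else 0
                if 1 + inner + right == target:
                    pairs.add((i + 1, k + 1))
                    stack.append((i + 1, k - 1))
                    if k < j:
                        stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    return SecondaryStructure(
        sequence=seq,
        pairs=frozenset(pairs),
        dot_bracket=pairs_to_dot_bracket(pairs, n),
    )


def structure_delta(
    seq: str,
    edit_position: int,
    base_before: str,
    base_after: str,
    min_loop: int = 3,
    allow_gu: bool = True,
) -> tuple[SecondaryStructure, SecondaryStructure, int]:
    """Fold a sequence before and after a single-base edit.

    Returns the two structures and the size of the symmetric difference of
    their pair sets (0 means the edit left the predicted pairing untouched).
    """
    rna = seq.upper().replace("T", "U")
    before = base_before.upper().replace("T", "U")
    after = base_after.upper().replace("T", "U")
    if not 1 <= edit_position <= len(rna):
        raise ValueError("edit_position out of range")
    if rna[edit_position - 1] != before:
        raise ValueError(
            f"sequence has {rna[edit_position - 1]} at position {edit_position}, "
            f"not {base_before}"
        )
    if before == after:
        raise ValueError("base_before and base_after must differ")
    edited = rna[: edit_position - 1] + after + rna[edit_position:]
    s_before = fold(rna, min_loop=min_loop, allow_gu=allow_gu)
    s_after = fold(edited, min_loop=min_loop, allow_gu=allow_gu)
    changed = len(s_before.pairs ^ s_after.pairs)
    return s_before, s_after, changed


def write_vienna(structure: SecondaryStructure, path: str | Path, name: str = "seq") -> None:
    """Write sequence + dot-bracket in Vienna format."""
    with open(path, "w") as fh:
        fh.write(f">{name}\n{structure.sequence}\n{structure.dot_bracket}\n")
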