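"""Unit-cost Levenshtein distance and nearest-training-peptide resolution.

Used to route peptides unseen during training to the closest training
peptide, whose positional-preference map stands in for the unknown one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = ["EditDistanceResult", "edit_distance", "nearest_training_peptide"]


@dataclass(frozen=True)
class EditDistanceResult:
    distance: int
    query: str
    match: str


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance: minimal single-character insertions, deletions
    and substitutions (all cost 1) transforming ``a`` into ``b``.

    Standard dynamic programme over two rows; O(len(a)*len(b)) time,
    O(min-row) space.
    """
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        curr = [i] + [0] * len(b)
        for j, cb in enumerate(b, start=1):
            curr[j] = min(
                prev[j] + 1,        # deletion
                curr[j - 1] + 1,    # insertion
                prev[j - 1] + (ca != cb),  # substitution
            )
        prev = curr
    return prev[-1]


def nearest_training_peptide(query: str, candidates: Iterable[str]) -> EditDistanceResult:
    """Candidate at minimum edit distance from ``query``.

    Ties are broken by lexicographically smallest candidate so the result
    is independent of candidate order.
    """
    best: str | None = None
    best_d = -1
    for cand in candidates:
        d = edit_distance(query, cand)
        if best is None or d < best_d or (d == best_d and cand < best):
            best, best_d = cand, d
    if best is None:
        raise ValueError("candidate set must be non-empty")
    return EditDistanceResult(distance=best_d, query=query, match=best)
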