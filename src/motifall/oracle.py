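"""Brute-force reference: exhaustive motif enumeration and mining.

Certifies completeness and soundness of the level-wise miner on small
instances by enumerating the entire motif space — (a+1)^(L-1) - 1 patterns for
an a-letter alphabet — and filtering by support and significance directly.
Guarded against use beyond enumerable sizes.
"""

from __future__ import annotations

from itertools import combinations, product
from typing import Iterator

from .alphabet import AMINO_ACIDS
from .mining import frequent_threshold
from .motif import Motif, support_count
from .peptides import PeptideSet
from .stats import ScoredMotif, score_motifs

__all__ = ["enumerate_all_motifs", "brute_force_mine", "motif_space_size"]

_MAX_ENUMERABLE = 2_000_000


def motif_space_size(L: int, alphabet: str) -> int:
    """(a+1)^(L-1) - 1: every non-center position is a wildcard or one of a letters."""
    return (len(alphabet) + 1) ** (L - 1) - 1


def enumerate_all_motifs(
    L: int,
    alphabet: str,
    acceptor: str,
    max_k: int | None = None,
) -> Iterator[Motif]:
    """Yield every distinct motif with 1 <= k <= max_k, without duplicates.

    Errors when the full space exceeds the enumerable bound — this is a test
    oracle, never a substitute for the level-wise miner at real scale.
    """
    if L < 3 or L % 2 == 0:
        raise ValueError(f"window length must be odd and >= 3, got {L}")
    total = motif_space_size(L, alphabet)
    if total > _MAX_ENUMERABLE:
        raise ValueError(
            f"motif space of size {total} exceeds the enumerable bound {_MAX_ENUMERABLE}"
        )
    center = (L - 1) // 2
    positions = [p for p in range(L) if p != center]
    cap = L - 1 if max_k is None else min(max_k, L - 1)
    for k in range(1, cap + 1):
        for pos_combo in combinations(positions, k):
            for residues in product(alphabet, repeat=k):
                yield Motif(tuple(zip(pos_combo, residues)), L, acceptor)


def brute_force_mine(
    P: PeptideSet,
    N: PeptideSet,
    s: float | str,
    theta: float,
    alphabet: str = AMINO_ACIDS,
    max_k: int | None = None,
    two_sided: bool = False,
) -> list[ScoredMotif]:
    """Ground truth: exhaustively filter the whole motif space by support,
    then score survivors with the same statistics stage."""
    if len(P) == 0:
        raise ValueError("cannot mine an empty foreground set")
    centers = {seq[P.center_index] for seq in P}
    if len(centers) != 1:
        raise ValueError("brute-force mining requires a single-acceptor foreground")
    acceptor = next(iter(centers))
    t = frequent_threshold(s, len(P))
    frequent = {}
    for m in enumerate_all_motifs(P.L, alphabet, acceptor, max_k=max_k):
        c = support_count(m, P)
        if c >= t:
            frequent[m] = c
    return score_motifs(frequent, P, N, theta=theta, two_sided=two_sided)
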