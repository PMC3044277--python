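"""Stage 1: level-wise (Apriori-style) mining of all frequent motifs.

A motif is *frequent* when at least a fraction ``s`` of the foreground
peptides carry it.  Support is anti-monotone — a motif can never be more
frequent than any of its generalizations — so the search runs level by level
over motif size k: frequent 1-motifs seed the search, candidates of size k are
built only from frequent (k-1)-motifs, and each level is counted in a single
pass over the foreground.  The search stops when a level comes back empty,
and the union of all levels is exactly the set of frequent motifs (complete
and sound; the brute-force oracle certifies this on enumerable instances).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

import numpy as np

from .motif import Motif
from .peptides import PeptideSet

__all__ = [
    "MiningConfig",
    "FrequentLevel",
    "frequent_threshold",
    "level1",
    "generate_candidates",
    "mine_frequent",
]


@dataclass(frozen=True)
class MiningConfig:
    """Mining parameters: support fraction ``s`` and optional size cap ``max_k``.

    ``max_k`` defaults to L-1 (uncapped); the level-wise search normally
    terminates on its own when a level is empty.
    """

    s: float | str | Fraction
    max_k: int | None = None

    def __post_init__(self) -> None:
        frac = _as_fraction(self.s)
        if not (0 < frac <= 1):
            raise ValueError(f"support threshold must lie in (0, 1], got {self.s}")
        if self.max_k is not None and self.max_k < 1:
            raise ValueError(f"max_k must be >= 1, got {self.max_k}")


@dataclass
class FrequentLevel:
    """All frequent k-motifs of one level, with their foreground support counts."""

    k: int
    motifs: dict[Motif, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.motifs)

    def __contains__(self, m: Motif) -> bool:
        return m in self.motifs

    def __iter__(self):
        return iter(self.motifs)


def _as_fraction(s: float | str | Fraction) -> Fraction:
    """Exact rational form of a support threshold.

    Decimal strings like ``"0.08"`` convert exactly; floats are snapped to the
    nearest small-denominator rational so that e.g. ``0.08`` means 2/25 rather
    than its binary approximation.  This keeps threshold counts free of
    floating-point boundary artifacts.
    """
    if isinstance(s, Fraction):
        return s
    if isinstance(s, str):
        return Fraction(s)
    if isinstance(s, (int, np.integer)):
        return Fraction(int(s))
    return Fraction(float(s)).limit_denominator(10**9)


def frequent_threshold(s: float | str | Fraction, n: int) -> int:
    """Minimum foreground match count equivalent to support fraction ``s`` on
    a foreground of ``n`` peptides.

    The count is the nearest integer to ``n*s`` (halves round up), clamped to
    at least 1 — the rounding that reproduces the published occurrence
    equivalents of a percentage support threshold (e.g. 8% of 2734, 415 and 80
    peptides gives 219, 33 and 6).  Computed in exact rational arithmetic.
    """
    if n < 1:
        raise ValueError(f"foreground size must be >= 1, got {n}")
    frac = _as_fraction(s)
    if not (0 < frac <= 1):
        raise ValueError(f"support threshold must lie in (0, 1], got {s}")
    x = frac * n
    t = int(x + Fraction(1, 2))  # floor(x + 1/2): nearest integer, half up
    return max(t, 1)


def level1(P: PeptideSet, s: float | str | Fraction) -> FrequentLevel:
    """All frequent 1-motifs, counted in a single scan of the foreground.

    Every (position, residue) cell with position != center and residue an
    amino-acid letter observed in ``P`` is a candidate; the pad symbol never
    supports a conserved position.  Requires a single-acceptor set.
    """
    if len(P) == 0:
        raise ValueError("cannot mine an empty foreground set")
    center_letter = _single_acceptor(P)
    t = frequent_threshold(s, len(P))
    arr = P.matrix
    out: dict[Motif, int] = {}
    for pos in range(P.L):
        if pos == P.center_index:
            continue
        residues, counts = np.unique(arr[:, pos], return_counts=True)
        for res, cnt in zip(residues, counts):
            res = str(res)
            if not (res.isalpha() and res.isupper()):
                continue  # pad or filler never seeds a conserved position
            if cnt >= t:
                out[Motif({pos: res}, P.L, center_letter)] = int(cnt)
    return FrequentLevel(1, dict(sorted(out.items(), key=lambda kv: kv[0].conserved)))


def generate_candidates(F_prev: FrequentLevel, F1: FrequentLevel) -> set[Motif]:
    """Candidate k-motifs whose every (k-1)-generalization is frequent.

    Each frequent (k-1)-motif is extended with a frequent 1-motif at a position
    strictly beyond its last conserved position (so each candidate is built
    exactly once), then candidates with any infrequent (k-1)-generalization
    are pruned.  Anti-monotonicity guarantees no frequent k-motif is missed.
    """
    if F_prev.k < 1:
        raise ValueError("previous level must have k >= 1")
    prev = set(F_prev.motifs)
    items = [m.conserved[0] for m in F1.motifs]
    out: set[Motif] = set()
    for m in F_prev:
        last_pos = m.conserved[-1][0]
        for pos, res in items:
            if pos <= last_pos:
                continue
            cand = m.extend(pos, res)
            if all(g in prev for g in cand.generalizations()):
                out.add(cand)
    return out


def mine_frequent(
    P: PeptideSet,
    s: float | str | Fraction,
    max_k: int | None = None,
) -> list[FrequentLevel]:
    """Level-wise search for all frequent motifs in the foreground.

    Returns the non-empty levels F_1, F_2, ... with exact support counts
    attached; stops when a level is empty or ``max_k`` is reached.
    """
    cfg = MiningConfig(s, max_k)
    cap = P.L - 1 if cfg.max_k is None else min(cfg.max_k, P.L - 1)
    t = frequent_threshold(s, len(P))
    F1 = level1(P, s)
    if len(F1) == 0:
        return []
    levels = [F1]
    arr = P.matrix
    center_letter = _single_acceptor(P)
    cmask = arr[:, P.center_index] == center_letter
    # item masks are reused across levels: support of a candidate is the AND
    # of its 1-motif column masks, counted in one vectorized pass
    item_masks = {
        m.conserved[0]: cmask & (arr[:, m.conserved[0][0]] == m.conserved[0][1])
        for m in F1
    }
    while levels[-1].k < cap:
        candidates = generate_candidates(levels[-1], F1)
        if not candidates:
            break
        frequent: dict[Motif, int] = {}
        for cand in sorted(candidates, key=lambda m: m.conserved):
            mask = item_masks[cand.conserved[0]]
            for pair in cand.conserved[1:]:
                mask = mask & item_masks[pair]
            cnt = int(np.count_nonzero(mask))
            if cnt >= t:
                frequent[cand] = cnt
        if not frequent:
            break
        levels.append(FrequentLevel(levels[-1].k + 1, frequent))
    return levels


def _single_acceptor(P: PeptideSet) -> str:
    """The unique central residue of ``P``; mixed sets are mined per acceptor."""
    c = P.center_index
    letters = {seq[c] for seq in P}
    if len(letters) != 1:
        raise ValueError(
            f"mining requires a single-acceptor peptide set, found centers {sorted(letters)}; "
            "partition with PeptideSet.subset_by_center first"
        )
    return next(iter(letters))
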