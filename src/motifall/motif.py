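"""Pattern-based phosphorylation motifs: matching, support, generalization, text format.

A motif is a consensus pattern over a fixed window of length ``L``: a central
phospho-acceptor residue plus ``k`` conserved (position, residue) pairs; every
other position is a wildcard that matches any residue.  ``k`` is the motif
*size* — the center does not count towards it.  In text form wildcards are
``.`` and the center is written as the lowercase acceptor letter, so
``"D...s..P."`` (L = 9) is the 2-motif conserving D at position 0 and P at
position 7 around a phospho-serine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .alphabet import AMINO_ACID_SET, ACCEPTOR_SET, WILDCARD
from .peptides import Peptide, PeptideSet

__all__ = [
    "Motif",
    "MotifError",
    "matches",
    "support_count",
    "support_counts",
    "is_generalization",
    "render",
    "parse",
]


class MotifError(ValueError):
    """A motif violates the consensus-pattern contract."""


@dataclass(frozen=True)
class Motif:
    """An anchored consensus pattern with ``k = len(conserved)`` fixed positions.

    ``conserved`` is stored as a position-sorted tuple of ``(position, residue)``
    pairs, which makes equal motifs compare (and hash) equal and gives every
    motif a canonical form.  Positions are 0-based string indices; the center
    index ``(L-1)/2`` may not be conserved (the center residue is a separate,
    mandatory part of the motif).
    """

    conserved: tuple[tuple[int, str], ...]
    L: int
    center: str

    def __init__(
        self,
        conserved: Mapping[int, str] | Iterable[tuple[int, str]],
        L: int,
        center: str,
    ) -> None:
        if isinstance(conserved, Mapping):
            pairs = tuple(sorted(conserved.items()))
        else:
            pairs = tuple(sorted(conserved))
        object.__setattr__(self, "conserved", pairs)
        object.__setattr__(self, "L", L)
        object.__setattr__(self, "center", center.upper())
        self._validate()

    def _validate(self) -> None:
        if self.L < 3 or self.L % 2 == 0:
            raise MotifError(f"window length must be odd and >= 3, got {self.L}")
        if self.center not in ACCEPTOR_SET:
            raise MotifError(f"center residue must be one of S/T/Y, got {self.center!r}")
        if not (1 <= len(self.conserved) <= self.L - 1):
            raise MotifError(
                f"motif size must be between 1 and L-1={self.L - 1}, "
                f"got {len(self.conserved)}"
            )
        c = self.center_index
        seen: set[int] = set()
        for pos, res in self.conserved:
            if not (0 <= pos < self.L):
                raise MotifError(f"conserved position {pos} outside window of length {self.L}")
            if pos == c:
                raise MotifError(f"position {pos} is the center and cannot be conserved")
            if pos in seen:
                raise MotifError(f"position {pos} conserved twice")
            if res not in AMINO_ACID_SET:
                raise MotifError(
                    f"conserved residue must be an amino-acid letter, got {res!r} at {pos}"
                )
            seen.add(pos)

    @property
    def center_index(self) -> int:
        return (self.L - 1) // 2

    @property
    def k(self) -> int:
        """Motif size: number of conserved non-center positions."""
        return len(self.conserved)

    @property
    def conserved_dict(self) -> dict[int, str]:
        return dict(self.conserved)

    def generalizations(self) -> "list[Motif]":
        """All motifs of size k-1 obtained by dropping one conserved pair."""
        if self.k == 1:
            return []
        out = []
        for i in range(self.k):
            pairs = self.conserved[:i] + self.conserved[i + 1 :]
            out.append(Motif(pairs, self.L, self.center))
        return out

    def extend(self, pos: int, res: str) -> "Motif":
        return Motif(self.conserved + ((pos, res),), self.L, self.center)

    def __str__(self) -> str:
        return render(self)

    def __repr__(self) -> str:
        return f"Motif({render(self)!r})"


def matches(m: Motif, p: Peptide | str) -> bool:
    """True iff the peptide carries the motif.

    The peptide must show the motif's acceptor letter at the center and the
    conserved residue at every conserved position; wildcards are free.  The
    pad symbol satisfies only wildcards — a conserved position never matches a
    pad, so windows truncated at a protein terminus cannot spuriously carry a
    motif that reaches past the sequence end.
    """
    seq = str(p)
    if len(seq) != m.L:
        raise MotifError(f"peptide length {len(seq)} does not match motif L={m.L}")
    if seq[m.center_index] != m.center:
        return False
    return all(seq[pos] == res for pos, res in m.conserved)


def support_count(m: Motif, S: PeptideSet) -> int:
    """Number of peptides in ``S`` matching ``m`` (duplicates counted separately)."""
    if S.L != m.L:
        raise MotifError(f"peptide set L={S.L} does not match motif L={m.L}")
    if len(S) == 0:
        return 0
    arr = S.matrix
    mask = arr[:, m.center_index] == m.center
    for pos, res in m.conserved:
        mask &= arr[:, pos] == res
    return int(np.count_nonzero(mask))


def support_counts(motifs: Iterable[Motif], S: PeptideSet) -> dict[Motif, int]:
    """Support of many motifs against ``S`` in one pass over its residue matrix.

    Center-residue masks are shared across motifs with the same acceptor, which
    is what makes the single background scan of the scoring stage cheap.
    """
    arr = S.matrix
    center_masks: dict[str, np.ndarray] = {}
    out: dict[Motif, int] = {}
    for m in motifs:
        if S.L != m.L:
            raise MotifError(f"peptide set L={S.L} does not match motif L={m.L}")
        if len(S) == 0:
            out[m] = 0
            continue
        cmask = center_masks.get(m.center)
        if cmask is None:
            cmask = arr[:, m.center_index] == m.center
            center_masks[m.center] = cmask
        mask = cmask
        for pos, res in m.conserved:
            mask = mask & (arr[:, pos] == res)
        out[m] = int(np.count_nonzero(mask))
    return out


def is_generalization(g: Motif, m: Motif) -> bool:
    """True iff every conserved (position, residue) pair of ``g`` appears in ``m``.

    A generalization matches everything the more specific motif matches; the
    relation is reflexive.
    """
    if g.L != m.L or g.center != m.center:
        return False
    return set(g.conserved) <= set(m.conserved)


def render(m: Motif) -> str:
    """Motif as an L-character string: conserved letters, ``.`` wildcards,
    lowercase acceptor at the center (plain-text stand-in for underlining)."""
    chars = [WILDCARD] * m.L
    chars[m.center_index] = m.center.lower()
    for pos, res in m.conserved:
        chars[pos] = res
    return "".join(chars)


def parse(s: str, center_residue: str | None = None) -> Motif:
    """Inverse of :func:`render`; ``parse(render(m)) == m``.

    The central character must be a lowercase acceptor letter; when
    ``center_residue`` is given it must agree with it.  A string with no
    conserved position (all wildcards) is rejected — size-0 motifs carry no
    information beyond the acceptor itself.
    """
    L = len(s)
    if L < 3 or L % 2 == 0:
        raise MotifError(f"motif string length must be odd and >= 3, got {L}: {s!r}")
    c = (L - 1) // 2
    center = s[c]
    if not (center.isalpha() and center.islower() and center.upper() in ACCEPTOR_SET):
        raise MotifError(
            f"center marker must be a lowercase acceptor letter (s/t/y) at index {c}, "
            f"got {center!r} in {s!r}"
        )
    if center_residue is not None and center.upper() != center_residue.upper():
        raise MotifError(
            f"motif string centered on {center.upper()!r}, expected {center_residue.upper()!r}"
        )
    conserved: dict[int, str] = {}
    for i, ch in enumerate(s):
        if i == c or ch == WILDCARD:
            continue
        if not (ch.isalpha() and ch.isupper() and ch in AMINO_ACID_SET):
            raise MotifError(
                f"conserved residues must be uppercase amino-acid letters, "
                f"got {ch!r} at index {i} in {s!r}"
            )
        conserved[i] = ch
    if not conserved:
        raise MotifError(f"motif must conserve at least one non-center position: {s!r}")
    return Motif(conserved, L, center.upper())
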