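"""Centered phosphopeptide sets: validation, file IO and proteome-derived backgrounds.

A peptide here is a fixed-length window of ``L`` residues (``L`` odd) aligned so
that the phospho-acceptor residue (S, T or Y) sits at the central position.
Motif discovery contrasts a *foreground* set ``P`` of such windows around known
phosphosites against a *background* set ``N`` of windows around acceptor
residues not known to be phosphorylated.  The background is typically built by
sliding over a whole proteome, extracting every window centered on an acceptor
residue, and subtracting the foreground.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

from .alphabet import AMINO_ACID_SET, ACCEPTOR_SET, PAD

__all__ = [
    "Peptide",
    "PeptideSet",
    "PeptideError",
    "load_peptides",
    "build_background",
]


class PeptideError(ValueError):
    """A peptide record violates the fixed-length centered-window contract."""


def _normalize_acceptors(acceptor_class: Iterable[str] | str) -> frozenset[str]:
    acc = frozenset(str(a).upper() for a in acceptor_class)
    if not acc:
        raise PeptideError("acceptor class must contain at least one of S, T, Y")
    bad = acc - ACCEPTOR_SET
    if bad:
        raise PeptideError(
            f"acceptor class may only contain phospho-acceptor letters S/T/Y, got {sorted(bad)}"
        )
    return acc


def _check_window_length(L: int) -> None:
    if L < 3 or L % 2 == 0:
        raise PeptideError(f"window length must be an odd integer >= 3, got {L}")


def _validate_sequence(
    seq: str,
    L: int,
    acceptors: frozenset[str],
    where: str = "",
) -> None:
    """Raise :class:`PeptideError` unless ``seq`` is a valid centered window."""
    loc = f" ({where})" if where else ""
    if len(seq) != L:
        raise PeptideError(
            f"peptide has length {len(seq)}, expected {L}{loc}: {seq!r}"
        )
    center = (L - 1) // 2
    c = seq[center]
    if c not in acceptors:
        raise PeptideError(
            f"center residue {c!r} not in acceptor class {sorted(acceptors)}{loc}: {seq!r}"
        )
    for i, ch in enumerate(seq):
        if i == center:
            continue
        if ch not in AMINO_ACID_SET and ch != PAD:
            raise PeptideError(
                f"illegal character {ch!r} at position {i}{loc}: {seq!r}"
            )


@dataclass(frozen=True)
class Peptide:
    """A single fixed-length window centered on a phospho-acceptor residue."""

    sequence: str

    @property
    def L(self) -> int:
        return len(self.sequence)

    @property
    def center_index(self) -> int:
        return (len(self.sequence) - 1) // 2

    @property
    def center_residue(self) -> str:
        return self.sequence[self.center_index]

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return self.sequence


class PeptideSet:
    """An ordered, validated collection of equal-length centered peptides.

    Duplicates are retained: each entry is one observed peptide occurrence, and
    all counting downstream (support, contingency cells) is per occurrence.

    Parameters
    ----------
    sequences
        Peptide strings (or :class:`Peptide` objects); uppercased on ingest.
    L
        Shared window length.  Inferred from the first sequence when omitted.
    acceptor_class
        The allowed central residues, a subset of ``{'S', 'T', 'Y'}``.
    role
        ``"foreground"`` or ``"background"`` — informational only.
    """

    def __init__(
        self,
        sequences: Iterable[str | Peptide],
        L: int | None = None,
        acceptor_class: Iterable[str] | str = "STY",
        role: str = "foreground",
        validate: bool = True,
    ) -> None:
        if role not in ("foreground", "background"):
            raise ValueError(f"role must be 'foreground' or 'background', got {role!r}")
        seqs = [str(s).upper() for s in sequences]
        if L is None:
            if not seqs:
                raise PeptideError("cannot infer window length from an empty set")
            L = len(seqs[0])
        _check_window_length(L)
        acceptors = _normalize_acceptors(acceptor_class)
        if validate:
            for i, s in enumerate(seqs):
                _validate_sequence(s, L, acceptors, where=f"record {i + 1}")
        self._sequences = seqs
        self.L = L
        self.acceptor_class = acceptors
        self.role = role
        self._matrix: np.ndarray | None = None

    @property
    def sequences(self) -> list[str]:
        return list(self._sequences)

    @property
    def center_index(self) -> int:
        return (self.L - 1) // 2

    @property
    def matrix(self) -> np.ndarray:
        """Residue matrix of shape ``(n, L)``, dtype ``<U1`` (built lazily)."""
        if self._matrix is None:
            if self._sequences:
                m = np.array(self._sequences, dtype=f"U{self.L}")
                self._matrix = m.view("U1").reshape(len(self._sequences), self.L)
            else:
                self._matrix = np.empty((0, self.L), dtype="U1")
        return self._matrix

    def __len__(self) -> int:
        return len(self._sequences)

    def __iter__(self) -> Iterator[str]:
        return iter(self._sequences)

    def __getitem__(self, i: int) -> str:
        return self._sequences[i]

    def __repr__(self) -> str:
        return (
            f"PeptideSet(n={len(self)}, L={self.L}, "
            f"acceptors={''.join(sorted(self.acceptor_class))}, role={self.role!r})"
        )

    def subset_by_center(self, residue: str) -> "PeptideSet":
        """Peptides whose central residue equals ``residue`` (order preserved)."""
        residue = residue.upper()
        c = self.center_index
        return PeptideSet(
            [s for s in self._sequences if s[c] == residue],
            L=self.L,
            acceptor_class={residue},
            role=self.role,
            validate=False,
        )


def load_peptides(
    path: str | Path,
    L: int | None = None,
    acceptor_class: Iterable[str] | str = "STY",
    role: str = "foreground",
) -> PeptideSet:
    """Read a plain-text peptide list (one peptide per line).

    Blank lines and lines starting with ``#`` are ignored; remaining lines are
    uppercased and validated.  Errors name the offending line number.
    """
    path = Path(path)
    acceptors = _normalize_acceptors(acceptor_class)
    seqs: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            seq = line.upper()
            if L is None:
                L = len(seq)
                _check_window_length(L)
            _validate_sequence(seq, L, acceptors, where=f"{path.name}:{lineno}")
            seqs.append(seq)
    if L is None:
        raise PeptideError(f"no peptides found in {path}")
    return PeptideSet(seqs, L=L, acceptor_class=acceptors, role=role, validate=False)


def build_background(
    proteome: str | Path,
    L: int,
    acceptor_class: Iterable[str] | str,
    foreground: PeptideSet | None = None,
    pad: bool = False,
    pad_char: str = PAD,
) -> PeptideSet:
    """Extract all acceptor-centered ``L``-mers from a FASTA proteome.

    For every occurrence of an acceptor residue in every protein, the window of
    ``(L-1)/2`` flanking residues on each side is emitted.  Windows overhanging
    a terminus are completed with ``pad_char`` when ``pad`` is true, otherwise
    skipped.  Every window whose sequence exactly equals any foreground peptide
    is then removed; duplicates among the survivors are retained (each
    occurrence counts once).

    Raises on an empty FASTA; warns (and returns an empty set) when no window
    survives, since mining errors later on an empty background.
    """
    _check_window_length(L)
    acceptors = _normalize_acceptors(acceptor_class)
    if foreground is not None and foreground.L != L:
        raise PeptideError(
            f"foreground window length {foreground.L} does not match requested L={L}"
        )
    flank = (L - 1) // 2
    fg_seqs = frozenset(foreground.sequences) if foreground is not None else frozenset()

    windows: list[str] = []
    n_records = 0
    for record in SeqIO.parse(str(proteome), "fasta"):
        n_records += 1
        seq = str(record.seq).upper()
        for i, ch in enumerate(seq):
            if ch not in acceptors:
                continue
            lo, hi = i - flank, i + flank + 1
            if lo < 0 or hi > len(seq):
                if not pad:
                    continue
                left = pad_char * max(0, -lo)
                right = pad_char * max(0, hi - len(seq))
                window = left + seq[max(lo, 0) : min(hi, len(seq))] + right
            else:
                window = seq[lo:hi]
            if window in fg_seqs:
                continue
            windows.append(window)
    if n_records == 0:
        raise PeptideError(f"no FASTA records found in {proteome}")
    if not windows:
        warnings.warn(
            "background construction produced no peptides "
            "(mining will reject an empty background)",
            stacklevel=2,
        )
    return PeptideSet(
        windows, L=L, acceptor_class=acceptors, role="background", validate=False
    )
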