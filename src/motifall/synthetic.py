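"""Synthetic phosphopeptide sets with motifs planted at controlled frequencies.

The generator emulates the statistical structure the method assumes: a
foreground of centered phosphopeptides in which one or more motifs are
over-represented relative to a much larger background.  Residues at
unconstrained positions are drawn i.i.d. (uniform over the 20 amino acids by
default); each peptide independently carries each planted motif with the
set's plant frequency, in which case the motif's conserved residues are
written into the window.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alphabet import AMINO_ACIDS
from .motif import Motif, parse
from .peptides import PeptideSet

__all__ = ["PlantSpec", "generate", "parse_plant_spec"]


@dataclass(frozen=True)
class PlantSpec:
    """One motif to plant: carried by a fraction ``fg_freq`` of foreground and
    ``bg_freq`` of background peptides."""

    motif: Motif
    fg_freq: float
    bg_freq: float

    def __post_init__(self) -> None:
        for name, f in (("fg_freq", self.fg_freq), ("bg_freq", self.bg_freq)):
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {f}")


def parse_plant_spec(text: str, L: int, acceptor: str) -> PlantSpec:
    """Parse the ``MOTIF:FG_FREQ:BG_FREQ`` plant syntax, e.g. ``D...s...P:0.2:0.001``."""
    parts = text.split(":")
    if len(parts) != 3:
        raise ValueError(f"plant spec must be MOTIF:FG_FREQ:BG_FREQ, got {text!r}")
    m = parse(parts[0], center_residue=acceptor)
    if m.L != L:
        raise ValueError(f"plant motif length {m.L} does not match window length {L}")
    return PlantSpec(m, float(parts[1]), float(parts[2]))


def _check_specs(specs: Sequence[PlantSpec], L: int, acceptor: str, allow_overlap: bool) -> None:
    used: set[int] = set()
    for spec in specs:
        if spec.motif.L != L:
            raise ValueError(f"planted motif {spec.motif} has L={spec.motif.L}, expected {L}")
        if spec.motif.center != acceptor.upper():
            raise ValueError(
                f"planted motif centered on {spec.motif.center!r}, expected {acceptor.upper()!r}"
            )
        positions = {pos for pos, _ in spec.motif.conserved}
        if not allow_overlap and used & positions:
            raise ValueError(
                f"planted motifs share conserved positions {sorted(used & positions)}; "
                "pass allow_overlap=True to permit this"
            )
        used |= positions


def _sample_set(
    n: int,
    L: int,
    acceptor: str,
    specs: Sequence[PlantSpec],
    freqs: Sequence[float],
    rng: np.random.Generator,
    probs: np.ndarray | None,
    alphabet: str,
    role: str,
) -> PeptideSet:
    letters = np.array(list(alphabet))
    idx = rng.choice(len(letters), size=(n, L), p=probs)
    arr = letters[idx]
    arr[:, (L - 1) // 2] = acceptor
    for spec, freq in zip(specs, freqs):
        carry = rng.random(n) < freq
        for pos, res in spec.motif.conserved:
            arr[carry, pos] = res
    seqs = ["".join(row) for row in arr]
    return PeptideSet(seqs, L=L, acceptor_class={acceptor}, role=role, validate=False)


def generate(
    specs: Sequence[PlantSpec],
    n_foreground: int,
    n_background: int,
    L: int,
    acceptor: str = "S",
    seed: int = 0,
    residue_probs: Sequence[float] | None = None,
    alphabet: str = AMINO_ACIDS,
    allow_overlap: bool = False,
) -> tuple[PeptideSet, PeptideSet]:
    """Draw a (foreground, background) pair with the given motifs planted.

    ``residue_probs`` optionally biases the per-position residue distribution
    (one probability per letter of ``alphabet``); default is uniform.  Planted
    motifs must occupy disjoint conserved positions unless ``allow_overlap``.
    The same seed always reproduces the same pair of sets, byte for byte.
    """
    acceptor = acceptor.upper()
    _check_specs(specs, L, acceptor, allow_overlap)
    probs = None
    if residue_probs is not None:
        probs = np.asarray(residue_probs, dtype=float)
        if probs.shape != (len(alphabet),):
            raise ValueError(
                f"residue_probs must have one entry per alphabet letter ({len(alphabet)})"
            )
        probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    fg = _sample_set(
        n_foreground, L, acceptor, specs, [s.fg_freq for s in specs],
        rng, probs, alphabet, "foreground",
    )
    bg = _sample_set(
        n_background, L, acceptor, specs, [s.bg_freq for s in specs],
        rng, probs, alphabet, "background",
    )
    return fg, bg
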