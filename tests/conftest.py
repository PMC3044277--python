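"""Shared fixtures and helpers for the motifall test suite."""

from __future__ import annotations

import numpy as np
import pytest

from motifall import PeptideSet


def random_peptide_set(
    rng: np.random.Generator,
    n: int,
    L: int,
    alphabet: str,
    acceptor: str = "S",
    role: str = "foreground",
) -> PeptideSet:
    """Uniform i.i.d. peptides over an amino-acid sub-alphabet, acceptor-centered."""
    letters = np.array(list(alphabet))
    arr = letters[rng.integers(0, len(alphabet), size=(n, L))]
    arr[:, (L - 1) // 2] = acceptor
    return PeptideSet(
        ["".join(row) for row in arr],
        L=L,
        acceptor_class={acceptor},
        role=role,
        validate=False,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


@pytest.fixture
def tiny_foreground() -> PeptideSet:
    """Three serine-centered 3-mers with a duplicated sequence."""
    return PeptideSet(["ASA", "ASA", "CSA"], L=3, acceptor_class="S")
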