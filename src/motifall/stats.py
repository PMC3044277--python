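"""Stage 2: odds-ratio significance testing of frequent motifs against the background.

For each candidate motif m the four cells of a 2x2 contingency table are

    =============  =========  =============
                   carries m  does not
    foreground P   c00        c01
    background N   c10        c11
    =============  =========  =============

The odds ratio OR = (c00*c11)/(c01*c10) measures over-representation in the
foreground: OR = 1 means the motif is equally likely in both sets, OR > 1
means it is enriched among phosphorylated peptides.  Inference uses the
large-sample normal approximation of the log odds ratio: LOR = ln(OR),
SE = sqrt(1/c00 + 1/c01 + 1/c10 + 1/c11) (Woolf), z = LOR/SE ~ N(0, 1), and
the reported p-value is the one-sided upper tail P(Z >= z) — enrichment is
directional.  Tables with a zero cell get the Haldane–Anscombe correction
(+0.5 to all four cells) so the statistics stay finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple

from scipy.stats import norm

from .motif import Motif, render, support_count, support_counts
from .peptides import PeptideSet

__all__ = [
    "ContingencyTable",
    "ScoredMotif",
    "contingency",
    "haldane_correction",
    "odds_ratio",
    "log_odds_stats",
    "p_value",
    "score_motifs",
]


class ContingencyTable(NamedTuple):
    """Foreground/background match counts for one motif (c00+c01 = |P|, c10+c11 = |N|)."""

    c00: float
    c01: float
    c10: float
    c11: float


@dataclass(frozen=True)
class ScoredMotif:
    """A motif with its full contingency table and enrichment statistics."""

    motif: Motif
    table: ContingencyTable
    support: float  # c00 / |P|
    or_value: float
    lor: float
    se: float
    z: float
    p: float
    corrected: bool  # Haldane–Anscombe zero-cell adjustment applied

    def __str__(self) -> str:
        return (
            f"{render(self.motif)}  OR={self.or_value:.4g}  z={self.z:.3f}  p={self.p:.3e}"
        )


def contingency(m: Motif, P: PeptideSet, N: PeptideSet) -> ContingencyTable:
    """Count the four cells for motif ``m`` against foreground and background."""
    if len(P) == 0 or len(N) == 0:
        raise ValueError("contingency requires non-empty foreground and background")
    c00 = support_count(m, P)
    c10 = support_count(m, N)
    return ContingencyTable(c00, len(P) - c00, c10, len(N) - c10)


def haldane_correction(t: ContingencyTable) -> tuple[ContingencyTable, bool]:
    """Add 0.5 to all four cells when any cell is zero; report whether applied."""
    if min(t) > 0:
        return t, False
    return ContingencyTable(t.c00 + 0.5, t.c01 + 0.5, t.c10 + 0.5, t.c11 + 0.5), True


def odds_ratio(t: ContingencyTable) -> float:
    """Cross-product ratio (c00*c11)/(c01*c10) of the (possibly adjusted) cells.

    On raw tables a zero in c01 or c10 yields ``inf`` and a zero in c00 or c11
    yields 0.0, signalling that the caller skipped the zero-cell adjustment.
    """
    num = t.c00 * t.c11
    den = t.c01 * t.c10
    if den == 0:
        return math.nan if num == 0 else math.inf
    return num / den


def log_odds_stats(t: ContingencyTable) -> tuple[float, float, float]:
    """(LOR, SE, z) on effective cells: natural-log OR, Woolf standard error,
    and their ratio."""
    if min(t) <= 0:
        raise ValueError(
            "log-odds statistics need strictly positive cells; "
            "apply haldane_correction first"
        )
    lor = math.log(odds_ratio(t))
    se = math.sqrt(1 / t.c00 + 1 / t.c01 + 1 / t.c10 + 1 / t.c11)
    return lor, se, lor / se


def p_value(z: float, two_sided: bool = False) -> float:
    """Upper-tail normal probability P(Z >= z); optionally two-sided 2*P(Z >= |z|)."""
    if two_sided:
        return float(2.0 * norm.sf(abs(z)))
    return float(norm.sf(z))


def score_motif(m: Motif, t: ContingencyTable, n_fg: int, two_sided: bool = False) -> ScoredMotif:
    """Assemble the full statistics record for one motif from its raw table."""
    eff, corrected = haldane_correction(t)
    orv = odds_ratio(eff)
    lor, se, z = log_odds_stats(eff)
    return ScoredMotif(
        motif=m,
        table=t,
        support=t.c00 / n_fg,
        or_value=orv,
        lor=lor,
        se=se,
        z=z,
        p=p_value(z, two_sided=two_sided),
        corrected=corrected,
    )


def score_motifs(
    F: Mapping[Motif, int],
    P: PeptideSet,
    N: PeptideSet,
    theta: float = 1e-6,
    two_sided: bool = False,
    bonferroni: bool = False,
) -> list[ScoredMotif]:
    """Score every frequent motif against the background and keep p <= theta.

    ``F`` maps each frequent motif to its foreground count c00 from stage 1
    (never recounted); the background counts c10 for all motifs come from one
    shared pass over ``N``.  With ``bonferroni`` the significance threshold is
    divided by the number of motifs tested.  The result is deterministically
    ordered: p ascending, then foreground count descending, then motif string.
    """
    if not (0 < theta <= 1):
        raise ValueError(f"significance threshold must lie in (0, 1], got {theta}")
    if not F:
        return []
    if len(N) == 0:
        raise ValueError("scoring requires a non-empty background set")
    n_fg, n_bg = len(P), len(N)
    bg_counts = support_counts(F.keys(), N)
    cutoff = theta / len(F) if bonferroni else theta
    out: list[ScoredMotif] = []
    for m, c00 in F.items():
        t = ContingencyTable(c00, n_fg - c00, bg_counts[m], n_bg - bg_counts[m])
        sm = score_motif(m, t, n_fg, two_sided=two_sided)
        if sm.p <= cutoff:
            out.append(sm)
    out.sort(key=lambda sm: (sm.p, -sm.table.c00, render(sm.motif)))
    return out
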