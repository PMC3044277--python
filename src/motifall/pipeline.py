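"""The two-stage driver: frequent-motif mining, significance testing, reporting.

Stage 1 mines all frequent motifs from the (small) foreground alone; stage 2
makes a single pass over the (large) background to attach odds-ratio
statistics to each frequent motif and keeps those with p <= theta.  Splitting
the work this way means the expensive background is scanned once, for a
candidate set already reduced by the support constraint.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .mining import FrequentLevel, frequent_threshold, mine_frequent
from .motif import Motif, render
from .peptides import PeptideSet, build_background, load_peptides
from .stats import ScoredMotif, score_motifs

__all__ = [
    "RunConfig",
    "RunReport",
    "motif_all",
    "run_motif_all",
    "write_report",
    "REPORT_COLUMNS",
]

logger = logging.getLogger("motifall")

REPORT_COLUMNS = (
    "motif",
    "k",
    "c00",
    "c01",
    "c10",
    "c11",
    "support",
    "odds_ratio",
    "lor",
    "se",
    "z",
    "p_value",
    "corrected",
)


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; mirrors the CLI flags."""

    foreground: str | Path
    background: str | Path | None = None
    proteome: str | Path | None = None
    L: int | None = None
    acceptors: str = "STY"
    s: float | str = 0.05
    theta: float = 1e-6
    out: str | Path | None = None
    pad: bool = False
    two_sided: bool = False
    bonferroni: bool = False
    max_k: int | None = None

    def __post_init__(self) -> None:
        if (self.background is None) == (self.proteome is None):
            raise ValueError("provide exactly one of background or proteome")
        if not (0 < float(self.theta) <= 1):
            raise ValueError(f"significance threshold must lie in (0, 1], got {self.theta}")


@dataclass
class RunReport:
    """Per-run bookkeeping: set sizes, per-level counts, timings."""

    n_foreground: int = 0
    n_background: int = 0
    threshold_counts: dict[str, int] = field(default_factory=dict)
    level_counts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    n_frequent: int = 0
    n_significant: int = 0
    wall_seconds: float = 0.0

    def summary(self) -> str:
        lines = [
            f"foreground peptides : {self.n_foreground}",
            f"background peptides : {self.n_background}",
        ]
        for acc, t in self.threshold_counts.items():
            lines.append(f"support threshold [{acc}] : >= {t} foreground matches")
        for acc, levels in self.level_counts.items():
            per = ", ".join(f"k={k}: {n}" for k, n in levels) or "none"
            lines.append(f"frequent levels [{acc}] : {per}")
        lines.append(f"frequent motifs     : {self.n_frequent}")
        lines.append(f"significant motifs  : {self.n_significant}")
        lines.append(f"wall time           : {self.wall_seconds:.2f} s")
        return "\n".join(lines)


def motif_all(
    P: PeptideSet,
    N: PeptideSet,
    s: float | str,
    theta: float = 1e-6,
    max_k: int | None = None,
    two_sided: bool = False,
    bonferroni: bool = False,
) -> tuple[list[ScoredMotif], RunReport]:
    """Run both stages on in-memory peptide sets.

    Mixed-acceptor sets are partitioned by central residue and mined per
    acceptor; results are merged and sorted (p ascending, foreground count
    descending, motif string) so identical inputs always give identical
    output order.
    """
    if len(P) == 0:
        raise ValueError("foreground set is empty")
    if len(N) == 0:
        raise ValueError("background set is empty")
    if P.L != N.L:
        raise ValueError(f"foreground L={P.L} and background L={N.L} differ")
    t0 = time.perf_counter()
    report = RunReport(n_foreground=len(P), n_background=len(N))

    centers = sorted({seq[P.center_index] for seq in P})
    results: list[ScoredMotif] = []
    for acc in centers:
        P_acc = P.subset_by_center(acc) if len(centers) > 1 else P
        N_acc = N.subset_by_center(acc) if len(centers) > 1 else N
        report.threshold_counts[acc] = frequent_threshold(s, len(P_acc))
        levels = mine_frequent(P_acc, s, max_k=max_k)
        report.level_counts[acc] = [(lv.k, len(lv)) for lv in levels]
        frequent = {m: c for lv in levels for m, c in lv.motifs.items()}
        report.n_frequent += len(frequent)
        if not frequent:
            logger.info("no frequent motifs for acceptor %s", acc)
            continue
        if len(N_acc) == 0:
            raise ValueError(f"background contains no peptides centered on {acc}")
        results.extend(
            score_motifs(
                frequent, P_acc, N_acc, theta=theta,
                two_sided=two_sided, bonferroni=bonferroni,
            )
        )
    results.sort(key=lambda sm: (sm.p, -sm.table.c00, render(sm.motif)))
    report.n_significant = len(results)
    n_corrected = sum(sm.corrected for sm in results)
    if n_corrected:
        logger.warning("zero-cell correction applied to %d motif(s)", n_corrected)
    report.wall_seconds = time.perf_counter() - t0
    logger.info("run complete:\n%s", report.summary())
    return results, report


def run_motif_all(cfg: RunConfig) -> tuple[list[ScoredMotif], RunReport]:
    """File-level driver: load inputs, optionally build the background from a
    proteome, run both stages, and write the TSV report when requested."""
    P = load_peptides(cfg.foreground, L=cfg.L, acceptor_class=cfg.acceptors, role="foreground")
    if cfg.background is not None:
        N = load_peptides(cfg.background, L=P.L, acceptor_class=cfg.acceptors, role="background")
    else:
        N = build_background(
            cfg.proteome, L=P.L, acceptor_class=cfg.acceptors,
            foreground=P, pad=cfg.pad,
        )
    results, report = motif_all(
        P, N, s=cfg.s, theta=cfg.theta, max_k=cfg.max_k,
        two_sided=cfg.two_sided, bonferroni=cfg.bonferroni,
    )
    if cfg.out is not None:
        write_report(results, cfg.out)
    return results, report


def write_report(results: Sequence[ScoredMotif], path: str | Path) -> None:
    """Write scored motifs as a TSV table, one row per motif.

    Fixed column order and number formats ('\\n' endings, support to 6
    decimals, p-value in 4-significant-digit scientific notation) make the
    file byte-identical across runs on identical input.
    """
    path = Path(path)
    lines = ["\t".join(REPORT_COLUMNS)]
    for sm in results:
        t = sm.table
        lines.append(
            "\t".join(
                (
                    render(sm.motif),
                    str(sm.motif.k),
                    _cell(t.c00),
                    _cell(t.c01),
                    _cell(t.c10),
                    _cell(t.c11),
                    f"{sm.support:.6f}",
                    f"{sm.or_value:.6g}",
                    f"{sm.lor:.6g}",
                    f"{sm.se:.6g}",
                    f"{sm.z:.6g}",
                    f"{sm.p:.3e}",
                    "true" if sm.corrected else "false",
                )
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def _cell(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:g}"
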