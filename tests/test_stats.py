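"""Odds-ratio machinery: contingency tables, LOR/SE/z, p-values, motif scoring."""

from __future__ import annotations

import math

import numpy as np
import pytest

from motifall import (
    ContingencyTable,
    Motif,
    PeptideSet,
    contingency,
    haldane_correction,
    log_odds_stats,
    odds_ratio,
    p_value,
    score_motifs,
)
from motifall.synthetic import PlantSpec, generate
from motifall.motif import parse, render, support_count

from conftest import random_peptide_set

REL = 1e-12


class TestContingency:
    def test_extreme_table(self):
        P = PeptideSet(["ACCCSCCCC"] * 5, L=9, acceptor_class="S")
        N = PeptideSet(["CCCCSCCCC"] * 7, L=9, acceptor_class="S", role="background")
        t = contingency(Motif({0: "A"}, 9, "S"), P, N)
        assert t == (5, 0, 0, 7)

    def test_row_sums_are_set_sizes(self, rng):
        P = random_peptide_set(rng, 25, 7, "ACDE")
        N = random_peptide_set(rng, 80, 7, "ACDE", role="background")
        for _ in range(20):
            pos = int(rng.choice([0, 1, 2, 4, 5, 6]))
            res = str(rng.choice(list("ACDE")))
            t = contingency(Motif({pos: res}, 7, "S"), P, N)
            assert t.c00 + t.c01 == len(P)
            assert t.c10 + t.c11 == len(N)
            assert min(t) >= 0

    def test_empty_sets_rejected(self):
        P = PeptideSet(["ASA"], L=3, acceptor_class="S")
        empty = PeptideSet([], L=3, acceptor_class="S", role="background")
        with pytest.raises(ValueError):
            contingency(Motif({0: "A"}, 3, "S"), P, empty)

    def test_planted_frequency_recovered(self):
        spec = PlantSpec(parse("D...s...."), fg_freq=0.3, bg_freq=0.01)
        fg, bg = generate([spec], 600, 600, 9, seed=11)
        t = contingency(spec.motif, fg, bg)
        # expected carrier fraction: 0.3 + 0.7/20 (uniform background hits)
        expected = 0.3 + 0.7 / 20
        se = math.sqrt(expected * (1 - expected) / 600)
        assert abs(t.c00 / 600 - expected) < 4 * se


class TestOddsRatio:
    def test_hand_arithmetic(self):
        assert odds_ratio(ContingencyTable(10, 90, 100, 9900)) == pytest.approx(11.0, rel=REL)

    def test_balanced_tables_give_one(self):
        assert odds_ratio(ContingencyTable(5, 5, 5, 5)) == pytest.approx(1.0, rel=REL)
        assert odds_ratio(ContingencyTable(2, 4, 10, 20)) == pytest.approx(1.0, rel=REL)

    def test_raw_zero_cells_signalled(self):
        assert odds_ratio(ContingencyTable(5, 0, 3, 7)) == math.inf
        assert odds_ratio(ContingencyTable(0, 5, 3, 7)) == 0.0

    def test_haldane_correction_applies_only_on_zeros(self):
        t, corrected = haldane_correction(ContingencyTable(5, 0, 3, 7))
        assert corrected and t == (5.5, 0.5, 3.5, 7.5)
        t2, corrected2 = haldane_correction(ContingencyTable(5, 1, 3, 7))
        assert not corrected2 and t2 == (5, 1, 3, 7)


class TestLogOddsStats:
    def test_hand_arithmetic(self):
        lor, se, z = log_odds_stats(ContingencyTable(10, 90, 100, 9900))
        assert lor == pytest.approx(math.log(11.0), rel=REL)
        # 1/10 + 1/90 + 1/100 + 1/9900 = 4/33
        assert se == pytest.approx(math.sqrt(4 / 33), rel=REL)
        assert z == pytest.approx(math.log(11.0) / math.sqrt(4 / 33), rel=REL)

    def test_or_one_collapses_to_zero(self):
        lor, se, z = log_odds_stats(ContingencyTable(5, 5, 5, 5))
        assert lor == pytest.approx(0.0, abs=REL)
        assert z == pytest.approx(0.0, abs=REL)

    def test_transposition_antisymmetry(self):
        t = ContingencyTable(12, 34, 56, 78)
        swapped = ContingencyTable(34, 12, 78, 56)
        lor, se, z = log_odds_stats(t)
        lor2, se2, z2 = log_odds_stats(swapped)
        assert lor2 == pytest.approx(-lor, rel=REL)
        assert se2 == pytest.approx(se, rel=REL)
        assert z2 == pytest.approx(-z, rel=REL)
        assert odds_ratio(swapped) == pytest.approx(1 / odds_ratio(t), rel=REL)

    def test_doubling_cells_preserves_lor_and_halves_variance(self):
        t = ContingencyTable(12, 34, 56, 78)
        doubled = ContingencyTable(24, 68, 112, 156)
        lor, se, _ = log_odds_stats(t)
        lor2, se2, _ = log_odds_stats(doubled)
        assert lor2 == pytest.approx(lor, rel=REL)
        assert se2**2 == pytest.approx(se**2 / 2, rel=REL)

    def test_zero_cell_requires_correction(self):
        with pytest.raises(ValueError, match="haldane"):
            log_odds_stats(ContingencyTable(5, 0, 3, 7))


class TestPValue:
    def test_symmetry_point(self):
        assert p_value(0.0) == pytest.approx(0.5, rel=REL)

    def test_tail_limits_and_monotonicity(self):
        assert p_value(40.0) < 1e-300
        assert p_value(-40.0) == pytest.approx(1.0, rel=1e-12)
        zs = np.linspace(-4, 4, 33)
        ps = [p_value(z) for z in zs]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_standard_quantile(self):
        assert p_value(1.6449) == pytest.approx(0.05, abs=1e-4)

    def test_two_sided_doubles_the_tail(self):
        assert p_value(1.96, two_sided=True) == pytest.approx(2 * p_value(1.96), rel=REL)
        assert p_value(-1.96, two_sided=True) == pytest.approx(
            p_value(1.96, two_sided=True), rel=REL
        )


class TestScoreMotifs:
    def _frequent(self, P, motifs):
        return {m: support_count(m, P) for m in motifs}

    def test_theta_one_keeps_everything(self, rng):
        P = random_peptide_set(rng, 30, 7, "ACDE")
        N = random_peptide_set(rng, 100, 7, "ACDE", role="background")
        F = self._frequent(P, [Motif({0: "A"}, 7, "S"), Motif({1: "C"}, 7, "S")])
        out = score_motifs(F, P, N, theta=1.0)
        assert {sm.motif for sm in out} == set(F)
        for sm in out:
            assert sm.z == pytest.approx(sm.lor / sm.se, rel=1e-9)
            assert 0 <= sm.p <= 1

    def test_planted_overexpressed_motif_passes_strict_threshold(self):
        spec = PlantSpec(parse("D...s...P"), fg_freq=0.2, bg_freq=0.001)
        fg, bg = generate([spec], 500, 50000, 9, seed=3)
        F = self._frequent(fg, [spec.motif])
        out = score_motifs(F, fg, bg, theta=1e-6)
        assert [sm.motif for sm in out] == [spec.motif]
        assert out[0].or_value > 1

    def test_deterministic_ordering(self, rng):
        P = random_peptide_set(rng, 30, 7, "ACDE")
        N = random_peptide_set(rng, 200, 7, "ACDE", role="background")
        F = self._frequent(
            P, [Motif({pos: res}, 7, "S") for pos in (0, 1, 2) for res in "ACDE"]
        )
        out = score_motifs(F, P, N, theta=1.0)
        keys = [(sm.p, -sm.table.c00, render(sm.motif)) for sm in out]
        assert keys == sorted(keys)

    def test_bonferroni_tightens_threshold(self, rng):
        P = random_peptide_set(rng, 30, 7, "ACDE")
        N = random_peptide_set(rng, 200, 7, "ACDE", role="background")
        F = self._frequent(
            P, [Motif({pos: res}, 7, "S") for pos in (0, 1) for res in "ACDE"]
        )
        plain = score_motifs(F, P, N, theta=0.5)
        strict = score_motifs(F, P, N, theta=0.5, bonferroni=True)
        assert {sm.motif for sm in strict} <= {sm.motif for sm in plain}
        for sm in strict:
            assert sm.p <= 0.5 / len(F)

    def test_null_motifs_mostly_excluded_at_five_percent(self):
        """With foreground and background drawn from the same distribution the
        one-sided test should reject near its nominal rate."""
        fg, bg = generate([], 2000, 20000, 9, seed=42)
        motifs = [
            Motif({pos: res}, 9, "S")
            for pos in range(9)
            if pos != 4
            for res in "ACDEFGHIKL"
        ]
        F = {m: support_count(m, fg) for m in motifs}
        out = score_motifs(F, fg, bg, theta=0.05)
        assert len(out) / len(F) <= 0.12

    def test_empty_background_rejected(self, rng):
        P = random_peptide_set(rng, 10, 7, "ACDE")
        empty = PeptideSet([], L=7, acceptor_class="S", role="background")
        with pytest.raises(ValueError, match="background"):
            score_motifs({Motif({0: "A"}, 7, "S"): 3}, P, empty, theta=1.0)
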