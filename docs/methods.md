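# Methods

## Model and procedure

The unit of data is a peptide window: a string of odd length `L` over the 20
amino-acid letters (plus an optional pad symbol `_`), aligned so that the
phospho-acceptor residue — serine, threonine or tyrosine — occupies the
central position `(L−1)/2`. A motif fixes the central acceptor plus `k ≥ 1`
conserved (position, residue) pairs at non-center positions; every other
position is a wildcard. The center contributes to neither the motif size `k`
nor the size of the pattern space, which is `(a+1)^(L−1) − 1` for an
`a`-letter alphabet (each non-center position is a wildcard or one letter;
the all-wildcard pattern is excluded).

Discovery is a two-stage filter:

1. **Support.** A motif is frequent when its foreground match count reaches
   `t(s, |P|)`, the occurrence equivalent of the support fraction `s`
   (below). Mining is level-wise over `k`: frequent 1-motifs are counted in
   one pass over `P`; candidates of size `k` are generated by extending each
   frequent `(k−1)`-motif with a frequent 1-motif at a strictly later
   position (each candidate is built exactly once) and pruned unless every
   `(k−1)`-generalization is frequent; each surviving level is counted in one
   vectorized pass; the search stops at the first empty level or at `max_k`
   (default `L−1`, i.e. no cap). Anti-monotonicity of support makes this
   complete: the union of levels is exactly `{m : support(m) ≥ t}`.

2. **Significance.** Each frequent motif's 2×2 table against the background
   gives `OR = (c00·c11)/(c01·c10)`, `LOR = ln OR`, Woolf's
   `SE = sqrt(Σ 1/c_ij)` and `z = LOR/SE`, treated as standard normal. The
   reported p-value is the one-sided upper tail `P(Z ≥ z)`: the question is
   over-representation in the foreground, and a two-sided test would also
   flag depletion. A `two_sided` option computes `2·P(Z ≥ |z|)` instead.
   Motifs with `p ≤ θ` are returned, sorted by p ascending, then foreground
   count descending, then motif string — a total order, so identical inputs
   always produce byte-identical reports.

Foreground `c00` counts are carried over from stage 1, never recounted; all
background counts come from one shared pass over `N`. Mixed-acceptor inputs
are partitioned by central residue and mined per acceptor, since a motif is
anchored on a single acceptor letter.

## Threshold rounding

The frequent/infrequent boundary `t(s, n)` is the **nearest integer** to
`n·s` (halves round up), clamped to at least 1, computed in exact rational
arithmetic (`Fraction`; decimal strings convert exactly, floats are snapped
to the nearest small-denominator rational). Nearest-integer rounding is the
rule under which a percentage support threshold and its published occurrence
equivalents coincide — 8% of 2734, 415 and 80 peptides giving 219, 33 and 6
matches respectively — whereas pure ceiling or floor each contradict one of
those triples. With `s = 1/|P|` the threshold is 1 and mining is exhaustive
over observed motifs.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `L` | window length (odd) | inferred from input | 21 and 13 are common choices in site databases |
| `s` | support fraction in (0, 1] | 0.05 (CLI) | trade-off between completeness and noise; 0.08–0.10 typical |
| `θ` | p-value cutoff | 1e-6 | raw p by default; `bonferroni` divides θ by the number of motifs tested |
| `max_k` | motif-size cap | none | search normally self-terminates |
| `pad` | keep terminus-overhanging windows | off | padded with `_`, which only wildcards match |

No multiple-testing correction is applied by default: the strict `θ = 1e-6`
convention already plays that role, and a Bonferroni option is available for
users who want family-wise control.

## Numerical choices and degenerate inputs

- **Zero cells.** Any zero in the 2×2 table triggers the Haldane–Anscombe
  correction (+0.5 to *all four* cells) before Eqs. for OR/LOR/SE, and the
  motif is flagged `corrected`. This keeps motifs absent from the background
  — often the most interesting ones — reportable with finite statistics. The
  raw (uncorrected) counts are what the report prints.
- **Pad semantics.** `_` satisfies only wildcards; a conserved position never
  matches a pad, so truncated windows cannot spuriously carry a motif that
  extends past the protein terminus, and pad-rich positions self-limit during
  mining.
- **Exact counting.** All supports are integer counts over occurrences
  (duplicates retained — the contingency cells are peptide counts, not
  unique-sequence counts); threshold comparisons are integer-vs-integer, so
  no float boundary can flip a motif's frequent status.
- **Empty sets.** An empty foreground or background is an error at
  mining/scoring time; a foreground subtraction that empties a
  proteome-derived background is a warning at construction time.
- **Determinism.** Candidate motifs carry a canonical position-sorted form,
  levels iterate in sorted order, and the final sort key is total, so runs
  are reproducible bit-for-bit.

## Synthetic data

The generator emulates the statistical structure the method assumes and
nothing more: peptides are i.i.d. uniform over the 20 amino acids at
unconstrained positions (an optional per-letter probability vector supports
compositional bias), the center is fixed to the acceptor, and each peptide
independently carries each planted motif with the set's plant frequency
(`fg_freq` in the foreground, `bg_freq` in the background), in which case the
conserved residues are written into the window. Plants must occupy disjoint
positions unless overlap is explicitly allowed. All draws come from one
seeded generator, so a seed fully reproduces both sets.

The default study conditions used throughout the tests are 500 foreground and
50 000 background peptides with `L = 9` and one motif planted at 20%
foreground / 0.1% background frequency — a regime where the expected z-score
clears the `θ = 1e-6` bar by a wide margin — plus a null variant with equal
plant frequencies in which nothing should pass.

What the generator does **not** model: realistic proteome amino-acid
composition, positional correlations, kinase-family structure, or ambiguity
in site localization. Passing tests therefore certify the algorithm and its
statistics, not performance on any particular organism's phosphoproteome.

## Verification strategy

The central correctness property is oracle equivalence: on instances small
enough to enumerate (`L ≤ 7`, alphabets up to 6 letters), the level-wise
miner plus scoring stage must return *exactly* — same motifs, same counts,
statistics to 1e-12 relative — what a brute-force scan of the entire
`(a+1)^(L−1) − 1` pattern space returns. The brute-force path
(`motifall.oracle`) shares only the primitive match/score operations with the
production path and none of the search logic; it refuses to run beyond an
enumerable bound. Property tests cover anti-monotonicity of support, downward
closure of the mined set, monotonicity in `s`, the render/parse round trip,
and the algebraic identities of the odds-ratio statistics (transposition
antisymmetry, variance halving under cell doubling, OR = 1 ⇒ z = 0 ⇒
p = 0.5). Test problem sizes (tens of foreground peptides against hundreds of
background peptides for oracle checks; 500 against 50 000 for the planted-
recovery scenario) were chosen so the whole suite runs in well under a minute
of CPU while keeping every binomial confidence band meaningful.

## Known limitations

- The normal approximation to the log odds ratio is a large-sample result;
  for very small cells the corrected estimate is finite but the p-value is
  approximate (an exact conditional test agrees in ranking on large-cell
  tables but is deliberately not the primary statistic).
- Motifs conserve exactly one residue per position; degenerate position
  classes such as `[ST]` are out of scope.
- Significance is assessed per motif on raw p-values; family-wise error
  control beyond the optional Bonferroni flag (e.g. permutation-based FDR) is
  not implemented.
- The miner's complexity is governed by the number of frequent motifs; very
  small `s` on large, highly conserved foregrounds can produce combinatorial
  result sets (that is the cost of completeness).
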