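"""How the support threshold controls the search.

Support is the fraction of foreground peptides matching a motif; a motif is
frequent when its match count reaches the occurrence equivalent of the
threshold s (the nearest integer to |P|*s).  Because support is anti-monotone
under specialization, raising s can only shrink the result set — and the
mined set at a higher threshold is always a subset of the set at a lower one.
"""

from motifall import frequent_threshold, mine_frequent, motif_all
from motifall.motif import parse
from motifall.synthetic import PlantSpec, generate

print("occurrence equivalents of an 8% support threshold:")
for n in (2734, 415, 80):
    print(f"  |P| = {n:>5}  ->  at least {frequent_threshold(0.08, n):>3} matching peptides")

plant = PlantSpec(parse("D...s...P"), fg_freq=0.25, bg_freq=0.01)
fg, bg = generate([plant], 300, 3000, L=9, acceptor="S", seed=7)

print("\nmined motifs by support threshold (same foreground):")
previous = None
for s in (0.05, 0.10, 0.20):
    motifs = {m for level in mine_frequent(fg, s) for m in level.motifs}
    nested = "" if previous is None else f"  (subset of s={previous}: {motifs <= prev_set})"
    print(f"  s = {s:.2f}: {len(motifs)} frequent motifs{nested}")
    previous, prev_set = s, motifs
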