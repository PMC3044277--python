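"""Build a background peptide set from a proteome FASTA file.

The background for motif discovery is every window of length L centered on a
phospho-acceptor residue anywhere in the proteome, minus the windows already
known to be phosphorylated (the foreground).  Windows that would overhang a
protein terminus are skipped by default, or completed with '_' when pad=True.
"""

import tempfile
from pathlib import Path

from motifall import PeptideSet, build_background

proteome = """\
>protein1
MKDASAPLWRRCCSCCHH
>protein2
SAQDKSAPW
"""

foreground = PeptideSet(["DASAP"], L=5, acceptor_class="S")

with tempfile.TemporaryDirectory() as tmp:
    fasta = Path(tmp) / "proteome.fa"
    fasta.write_text(proteome)

    skipped = build_background(fasta, L=5, acceptor_class={"S"}, foreground=foreground)
    padded = build_background(
        fasta, L=5, acceptor_class={"S"}, foreground=foreground, pad=True
    )

print("without padding:", skipped.sequences)
print("with padding:   ", padded.sequences)
print()
print(
    "Every window is a serine-centered 5-mer; DASAP is absent because it is\n"
    "already in the foreground, and the padded run additionally keeps the\n"
    "N-terminal serine of protein2 as '__SAQ'."
)
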