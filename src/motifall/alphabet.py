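"""Residue alphabet shared across the package.

Peptide windows are strings over the 20 standard amino-acid letters plus an
optional pad symbol used to complete windows that overhang a protein terminus.
Motif strings additionally use ``.`` for wildcard positions and a lowercase
acceptor letter to mark the central phospho residue.
"""

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
PHOSPHO_ACCEPTORS: str = "STY"
PAD: str = "_"
WILDCARD: str = "."

AMINO_ACID_SET = frozenset(AMINO_ACIDS)
ACCEPTOR_SET = frozenset(PHOSPHO_ACCEPTORS)
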