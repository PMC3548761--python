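"""Canonical amino-acid alphabets and index maps.

Everything downstream indexes residues in alphabetical one-letter order;
the AAindex flat-file order is translated at parse time only.
"""

ALPHABETICAL = "ACDEFGHIKLMNPQRSTVWY"
AAINDEX_ORDER = "ARNDCQEGHILKMFPSTWYV"

AA_TO_INDEX = {aa: i for i, aa in enumerate(ALPHABETICAL)}

# special (U, O) and ambiguous (B, Z, J, X) letters are rejected everywhere:
# they have no entry in a pairwise contact potential
NONCANONICAL = set("BZJUOX")


def is_canonical(sequence: str) -> bool:
    """True iff every letter is one of the 20 canonical residues."""
    return bool(sequence) and all(c in AA_TO_INDEX for c in sequence)
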