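"""Canonical amino-acid alphabet and sequence length bounds.

The residue-to-column order is fixed alphabetical so that saved models,
AAPP tables and feature maps are portable across runs and machines.
"""

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Curation length bounds (inclusive).
PEPTIDE_MIN_LEN = 8
PEPTIDE_MAX_LEN = 11
CDR3_MIN_LEN = 8
CDR3_MAX_LEN = 21

# Padded row counts used by the single-residue encoders: the peptide block
# occupies PEPTIDE_MAX_LEN rows, the CDR3 block CDR3_MAX_LEN rows, giving
# a 32-row concatenated pair representation.
PAIR_ROWS = PEPTIDE_MAX_LEN + CDR3_MAX_LEN

# AAPP covers CDR3 positions 2..21 (1-based); position 1 is the shared
# start cysteine and is excluded.
AAPP_POSITIONS = CDR3_MAX_LEN - 1


def is_valid_sequence(seq: str) -> bool:
    """True if ``seq`` is non-empty and uses only the 20 canonical letters."""
    return bool(seq) and all(c in AA_INDEX for c in seq)
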