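"""Nine-symbol vocabulary shared across the package.

The model operates on probability columns over nine symbols: five
structural tokens plus the four nucleotides. The ordering is fixed and is
part of every on-disk artifact, so it must never change:

index  0      1      2      3      4      5  6  7  8
token  [PAD]  [UNK]  [CLS]  [SEP]  [MASK] A  C  G  T
"""

PAD, UNK, CLS, SEP, MASK = 0, 1, 2, 3, 4
A, C, G, T = 5, 6, 7, 8

SYMBOLS = ("[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]", "A", "C", "G", "T")
VOCAB_SIZE = 9

#: rows 5..8 hold the nucleotide block (contiguous by construction)
NUC_SLICE = slice(5, 9)

BASES = "ACGT"
#: nucleotide letter -> row index in the 9-symbol space
BASE_TO_ROW = {"A": A, "C": C, "G": G, "T": T}
#: nucleotide letter -> index in a 4-vector allele distribution (A,C,G,T order)
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
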