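"""Parse and convert secondary-structure notations.

A three-strand structure is read from dot-parens-plus, rendered in the RLE
and DU+ shorthands, and its structure matrix (unit row/column sums, unpaired
bases on the diagonal) is printed.
"""

import numpy as np

from tubefold import parse_structure, structure_matrix, write_structure

s = parse_structure("((((....+))))((((+))))")
print("dot-parens-plus:", write_structure(s, "dpp"))
print("run-length enc.:", write_structure(s, "rle"))
print("DU+ notation:   ", write_structure(s, "du"))
print("strands:", s.n_strands, "| pairs:", len(s.pairs), "| nicks:", s.nicks)

S = structure_matrix(s)
print("structure matrix row sums:", np.unique(S.sum(axis=1)))
# every row and column sums to exactly 1: each base is either in one pair
# (off-diagonal 1) or unpaired (diagonal 1)
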