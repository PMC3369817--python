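"""Genetic-code lookup tables shared by the simulator and the codon-usage module.

The bacterial code (NCBI translation table 11) is used throughout; its
codon-to-amino-acid map is identical to the standard code, differing only in
permitted start codons, which play no role here.  All sequences are DNA
(``T``, not ``U``).
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[11]

#: The 61 sense codons in lexicographic order; stop codons are excluded from
#: every frequency computation.
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))

CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: The 20 proteinogenic amino acids, alphabetical one-letter codes.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: amino acid -> integer indices (into SENSE_CODONS) of its synonymous codons
AA_TO_CODON_IDX: dict[str, np.ndarray] = {
    aa: np.array([CODON_INDEX[c] for c in SENSE_CODONS if CODON_TO_AA[c] == aa])
    for aa in AMINO_ACIDS
}

#: (61, 61) 0/1 matrix; SYNONYM_MATRIX @ counts gives, per codon, the total
#: count of its synonym group (the per-amino-acid normalisation denominator).
SYNONYM_MATRIX: np.ndarray = np.zeros((len(SENSE_CODONS), len(SENSE_CODONS)))
for _aa, _idx in AA_TO_CODON_IDX.items():
    for _i in _idx:
        SYNONYM_MATRIX[_i, _idx] = 1.0

#: per sense codon, the integer index of the encoded amino acid
CODON_AA_IDX: np.ndarray = np.array(
    [AA_INDEX[CODON_TO_AA[c]] for c in SENSE_CODONS]
)
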