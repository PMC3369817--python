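"""All-vs-all protein similarity scoring.

The orthology stage consumes a *directed* table of local-alignment bit
scores.  Scores can come from the internal Smith-Waterman scorer (BLOSUM62,
affine gaps, raw scores converted to bits with the standard gapped
Karlin-Altschul parameters) or be imported from external tabular output such
as NCBI blast ``-outfmt 6``.  Hits below a 50-bit floor are rejected at table
construction, so best-hit queries range over surviving hits only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Iterable

from Bio import Align
from Bio.Align import substitution_matrices

from .model import Gene, Proteomes, flatten, strain_map

__all__ = [
    "AlignmentParams",
    "SimilarityTable",
    "local_align_bitscore",
    "make_scorer",
    "score_all_pairs",
    "load_external_scores",
    "write_scores",
]

#: Accepted protein alphabet; ``X`` (unknown residue) scores 0 against
#: everything, all other ambiguity codes are rejected.
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

DEFAULT_MIN_BITS = 50.0


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters of the internal local aligner.

    The defaults mirror the standard gapped protein-search setup: BLOSUM62
    with gap open 11 / gap extend 1 (a gap of length k costs 11 + k), and
    the corresponding gapped Karlin-Altschul parameters lambda = 0.267,
    K = 0.041 for the raw-score -> bit-score conversion
    ``bits = (lambda * S_raw - ln K) / ln 2``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041

    def raw_to_bits(self, raw: float) -> float:
        return (self.karlin_lambda * raw - math.log(self.karlin_k)) / math.log(2)


@lru_cache(maxsize=8)
def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    matrix = substitution_matrices.load(params.matrix_name).copy()
    if "X" in matrix.alphabet:
        for a in matrix.alphabet:
            matrix["X", a] = 0.0
            matrix[a, "X"] = 0.0
    aligner = Align.PairwiseAligner(mode="local")
    aligner.substitution_matrix = matrix
    # Biopython charges open_gap_score on a gap's first residue, so the
    # BLAST-style cost 11 + k per length-k gap maps to open -12 / extend -1.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _check_sequence(seq: str) -> None:
    if not seq:
        raise ValueError("empty protein sequence")
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(f"invalid residue(s) {sorted(bad)} in protein sequence")


def local_align_bitscore(
    seq_a: str, seq_b: str, params: AlignmentParams = AlignmentParams()
) -> float:
    """Smith-Waterman local-alignment score of two proteins, in bits.

    Symmetric in its arguments.  A pair with no positively scoring residue
    match has raw score 0 and therefore a bit score well below any useful
    floor.
    """
    _check_sequence(seq_a)
    _check_sequence(seq_b)
    raw = _aligner(params).score(seq_a, seq_b)
    return params.raw_to_bits(raw)


def make_scorer(params: AlignmentParams = AlignmentParams()) -> Callable[[str, str], float]:
    """A reusable pair-scorer closure over one configured aligner."""
    aligner = _aligner(params)

    def scorer(seq_a: str, seq_b: str) -> float:
        _check_sequence(seq_a)
        _check_sequence(seq_b)
        return params.raw_to_bits(aligner.score(seq_a, seq_b))

    return scorer


class SimilarityTable:
    """Directed gene-pair bit scores surviving the score floor.

    Self-pairs are never stored.  ``best_against(b, A)`` returns
    max over genes g of strain A of S(b, g) — the denominator of the
    bidirectional hit rate — and raises ``KeyError`` when no surviving hit
    of ``b`` against strain ``A`` exists.
    """

    def __init__(
        self,
        entries: dict[tuple[str, str], float],
        strain_of: dict[str, str],
        min_bits: float = DEFAULT_MIN_BITS,
    ):
        for (a, b), s in entries.items():
            if a == b:
                raise ValueError(f"self-pair ({a!r}, {a!r}) not allowed")
            if s < min_bits:
                raise ValueError(
                    f"entry ({a!r}, {b!r}) scores {s} below the {min_bits}-bit floor"
                )
            if a not in strain_of or b not in strain_of:
                missing = a if a not in strain_of else b
                raise ValueError(f"unknown gene id {missing!r} in score table")
        self._entries = dict(entries)
        self._strain_of = dict(strain_of)
        self.min_bits = float(min_bits)
        self._best: dict[tuple[str, str], float] = {}
        for (a, b), s in self._entries.items():
            key = (a, self._strain_of[b])
            if s > self._best.get(key, -math.inf):
                self._best[key] = s

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._entries

    def score(self, a: str, b: str) -> float | None:
        """Directed score S(a, b), or None if the hit did not survive."""
        return self._entries.get((a, b))

    def best_against(self, gene: str, strain: str) -> float:
        """Best surviving score of ``gene`` against any gene of ``strain``."""
        try:
            return self._best[(gene, strain)]
        except KeyError:
            raise KeyError(
                f"no surviving hit of gene {gene!r} against strain {strain!r}"
            ) from None

    def strain_of(self, gene: str) -> str:
        return self._strain_of[gene]

    @property
    def genes(self) -> tuple[str, ...]:
        """All gene ids of the universe (with or without surviving hits)."""
        return tuple(sorted(self._strain_of))

    @property
    def entries(self) -> dict[tuple[str, str], float]:
        return dict(self._entries)


def score_all_pairs(
    proteomes: Proteomes,
    scorer: Callable[[str, str], float] | None = None,
    min_bits: float = DEFAULT_MIN_BITS,
) -> SimilarityTable:
    """All-against-all comparison of every gene of every strain.

    Same-genome pairs are included: the downstream bidirectional hit rate
    caps, rather than excludes, within-genome hits.  ``scorer`` must be
    symmetric (the default internal scorer is); each unordered pair is
    scored once and stored in both directions when it survives the floor.
    """
    if len(proteomes) < 2:
        raise ValueError("need at least 2 strains")
    strains = strain_map(proteomes)  # raises on duplicate ids
    genes = flatten(proteomes)
    if scorer is None:
        scorer = make_scorer()
    entries: dict[tuple[str, str], float] = {}
    for i, ga in enumerate(genes):
        for gb in genes[i + 1 :]:
            bits = scorer(ga.protein, gb.protein)
            if bits >= min_bits:
                entries[(ga.id, gb.id)] = bits
                entries[(gb.id, ga.id)] = bits
    return SimilarityTable(entries, strains, min_bits=min_bits)


def load_external_scores(
    path: str,
    proteomes: Proteomes,
    min_bits: float = DEFAULT_MIN_BITS,
) -> SimilarityTable:
    """Import directed scores from a tabular file.

    Accepts either a 3-column (query, subject, bits) TSV or the 12-column
    blast tabular convention with the bit score in the final column.  Rows
    below ``min_bits`` are dropped; duplicate (query, subject) rows keep the
    maximum score; self-hit rows are ignored.
    """
    strains = strain_map(proteomes)
    entries: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 3:
                q, s, bits_str = fields
            elif len(fields) >= 12:
                q, s, bits_str = fields[0], fields[1], fields[11]
            else:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 or >=12 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                bits = float(bits_str)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric bit score {bits_str!r}"
                ) from None
            for gid in (q, s):
                if gid not in strains:
                    raise ValueError(f"{path}:{lineno}: unknown gene id {gid!r}")
            if q == s or bits < min_bits:
                continue
            key = (q, s)
            if bits > entries.get(key, -math.inf):
                entries[key] = bits
    return SimilarityTable(entries, strains, min_bits=min_bits)


def write_scores(table: SimilarityTable, path: str) -> None:
    """Write the directed table as a 3-column (query, subject, bits) TSV."""
    with open(path, "w") as fh:
        for (a, b) in sorted(table.entries):
            fh.write(f"{a}\t{b}\t{table.score(a, b):.6g}\n")
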