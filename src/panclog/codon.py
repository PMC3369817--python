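"""Codon-usage divergence between gene groups.

For a group g of genes, the usage f_t,g of a sense triplet t is the relative
frequency with which t encodes its amino acid, counted pooled across a random
selection of (by default) 100 distinct genes of length >= 50 aa.  Stop codons
are excluded throughout.  The squared divergence of two groups is

    d'^2_(i,j) = sum over all 61 sense triplets t of (f_t,i - f_t,j)^2,

and d^2_(i,j) averages d'^2 over (by default) 100 independent re-selections
of both groups.  For a strain x, the ratio

    r_x = d^2(core(x), unique(x)) / d^2(core(x), core(x))

compares the core-vs-unique codon divergence against the core group's own
selection noise; r_x >> 1 indicates that the strain's unique genes carry
atypical codon usage.  A two-sample Kolmogorov-Smirnov test on the two
replicate samples assesses significance.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._codons import CODON_INDEX, SENSE_CODONS, STOP_CODONS, SYNONYM_MATRIX

__all__ = [
    "GeneGroup",
    "CodonUsageProfile",
    "CodonDistanceResult",
    "codon_counts",
    "codon_frequency_profile",
    "codon_usage_distance",
    "codon_usage_ratio",
    "core_unique_ks_test",
    "per_strain_codon_table",
]

DEFAULT_N_SELECT = 100
DEFAULT_N_REPEATS = 100
DEFAULT_MIN_LEN_AA = 50

_DNA = frozenset("ACGT")


def codon_counts(cds: str, gene_id: str = "<cds>") -> np.ndarray:
    """Length-61 sense-codon count vector of one in-frame CDS.

    A single trailing stop codon is tolerated and stripped; internal stop
    codons or out-of-frame/invalid sequences are rejected.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"gene {gene_id!r}: CDS length {len(cds)} not a multiple of 3")
    if set(cds) - _DNA:
        raise ValueError(f"gene {gene_id!r}: CDS contains non-ACGT characters")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    counts = np.zeros(len(SENSE_CODONS), dtype=np.int64)
    for pos, c in enumerate(codons):
        if c in STOP_CODONS:
            raise ValueError(f"gene {gene_id!r}: internal stop codon at codon {pos}")
        counts[CODON_INDEX[c]] += 1
    return counts


class GeneGroup:
    """A group of genes with precomputed per-gene codon counts.

    Genes shorter than ``min_len_aa`` amino acids are excluded at
    construction, so selections always honour the length floor.
    """

    def __init__(
        self,
        group_id: str,
        gene_ids: list[str],
        counts: np.ndarray,
    ):
        if len(gene_ids) != counts.shape[0]:
            raise ValueError("gene_ids and counts disagree in length")
        self.group_id = group_id
        self.gene_ids = list(gene_ids)
        self.counts = counts  # (n_genes, 61) int

    @classmethod
    def from_cds(
        cls,
        group_id: str,
        cds_by_gene: dict[str, str],
        min_len_aa: int = DEFAULT_MIN_LEN_AA,
    ) -> "GeneGroup":
        ids, rows = [], []
        for gid in sorted(cds_by_gene):
            row = codon_counts(cds_by_gene[gid], gene_id=gid)
            if row.sum() >= min_len_aa:
                ids.append(gid)
                rows.append(row)
        if not ids:
            raise ValueError(
                f"group {group_id!r}: no eligible gene of >= {min_len_aa} aa"
            )
        return cls(group_id, ids, np.array(rows, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class CodonUsageProfile:
    """Relative synonymous-codon frequencies f_t,g of one gene selection."""

    group_id: str
    f: np.ndarray  # length 61; per amino acid, synonym frequencies sum to 1
    n_genes_used: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.f, index=list(SENSE_CODONS), name=self.group_id)


def _frequencies(total_counts: np.ndarray) -> np.ndarray:
    denom = SYNONYM_MATRIX @ total_counts
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(denom > 0, total_counts / np.where(denom > 0, denom, 1), 0.0)
    return f


def _select(group: GeneGroup, n_select: int, rng: np.random.Generator) -> np.ndarray:
    """Pooled codon counts of a random selection of distinct genes.

    Groups smaller than ``n_select`` contribute all their genes.
    """
    n = min(n_select, len(group))
    idx = rng.choice(len(group), size=n, replace=False)
    return group.counts[idx].sum(axis=0)


def codon_frequency_profile(
    group: GeneGroup,
    n_select: int = DEFAULT_N_SELECT,
    rng: np.random.Generator | int | None = None,
) -> CodonUsageProfile:
    """Codon-usage profile of one random gene selection within a group.

    Codon counts are pooled across the selected genes, then normalised per
    amino acid; amino acids absent from the selection carry frequency 0 for
    all their codons.
    """
    rng = np.random.default_rng(rng)
    n_used = min(n_select, len(group))
    total = _select(group, n_select, rng)
    return CodonUsageProfile(group.group_id, _frequencies(total), n_used)


@dataclass
class CodonDistanceResult:
    """Replicated squared codon-usage divergence of two groups."""

    group_i: str
    group_j: str
    d_sq: float  # mean of replicate_values
    replicate_values: np.ndarray

    def __post_init__(self) -> None:
        if (self.replicate_values < 0).any():
            raise ValueError("squared distances cannot be negative")


def codon_usage_distance(
    group_i: GeneGroup,
    group_j: GeneGroup,
    n_repeats: int = DEFAULT_N_REPEATS,
    n_select: int = DEFAULT_N_SELECT,
    rng: np.random.Generator | int | None = None,
) -> CodonDistanceResult:
    """d^2 between two gene groups.

    Each repeat independently re-selects genes within both groups, computes
    both profiles and the squared difference d'^2; d^2 is the average over
    repeats.  Comparing a group against itself measures pure selection
    noise; it is exactly 0 when the group has at most ``n_select`` genes,
    because both selections then cover the whole group.
    """
    rng = np.random.default_rng(rng)
    reps = np.empty(n_repeats)
    for r in range(n_repeats):
        f_i = _frequencies(_select(group_i, n_select, rng))
        f_j = _frequencies(_select(group_j, n_select, rng))
        reps[r] = float(((f_i - f_j) ** 2).sum())
    return CodonDistanceResult(
        group_i=group_i.group_id,
        group_j=group_j.group_id,
        d_sq=float(reps.mean()),
        replicate_values=reps,
    )


@dataclass
class StrainCodonResult:
    """Codon-usage comparison of one strain's core vs unique genes."""

    strain: str
    r_x: float
    d_core_core: CodonDistanceResult
    d_core_unique: CodonDistanceResult
    ks_statistic: float
    ks_p: float


def codon_usage_ratio(
    core_group: GeneGroup,
    unique_group: GeneGroup,
    n_repeats: int = DEFAULT_N_REPEATS,
    n_select: int = DEFAULT_N_SELECT,
    rng: np.random.Generator | int | None = None,
    strain: str = "",
) -> StrainCodonResult:
    """r_x = d^2(core, unique) / d^2(core, core) for one strain.

    Also runs the two-sample Kolmogorov-Smirnov test (asymptotic p) on the
    two replicate samples.  A zero core-core distance (possible only when
    codon usage is fully deterministic and selections identical) is an
    error.
    """
    rng = np.random.default_rng(rng)
    d_cc = codon_usage_distance(core_group, core_group, n_repeats, n_select, rng)
    d_cu = codon_usage_distance(core_group, unique_group, n_repeats, n_select, rng)
    if d_cc.d_sq == 0.0:
        raise ZeroDivisionError(
            f"strain {strain or core_group.group_id!r}: core-core distance is "
            "exactly 0; r_x undefined"
        )
    ks = stats.ks_2samp(d_cc.replicate_values, d_cu.replicate_values, method="asymp")
    return StrainCodonResult(
        strain=strain or core_group.group_id,
        r_x=d_cu.d_sq / d_cc.d_sq,
        d_core_core=d_cc,
        d_core_unique=d_cu,
        ks_statistic=float(ks.statistic),
        ks_p=float(ks.pvalue),
    )


def core_unique_ks_test(
    core_group: GeneGroup,
    unique_group: GeneGroup,
    n_repeats: int = DEFAULT_N_REPEATS,
    n_select: int = DEFAULT_N_SELECT,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Two-sample KS test of the core-core vs core-unique d'^2 replicates."""
    res = codon_usage_ratio(core_group, unique_group, n_repeats, n_select, rng)
    return res.ks_statistic, res.ks_p


def groups_from_labels(
    clogs,
    labels,
    cds_by_gene: dict[str, str],
    min_len_aa: int = DEFAULT_MIN_LEN_AA,
) -> dict[tuple[str, str], GeneGroup]:
    """Build (strain, class) gene groups from CLOG labels and CDS sequences.

    A gene inherits the core/shared/unique class of its CLOG.  Genes without
    a CDS, or shorter than the length floor, are dropped; (strain, class)
    combinations left empty are omitted.
    """
    label_of = labels.label_of()
    membership = clogs.membership()
    buckets: dict[tuple[str, str], dict[str, str]] = {}
    for gene, clog_id in membership.items():
        cds = cds_by_gene.get(gene)
        if cds is None:
            continue
        key = (clogs.strain_of[gene], label_of[clog_id])
        buckets.setdefault(key, {})[gene] = cds
    groups = {}
    for (strain, cls), cds_map in buckets.items():
        try:
            groups[(strain, cls)] = GeneGroup.from_cds(
                f"{strain}/{cls}", cds_map, min_len_aa=min_len_aa
            )
        except ValueError:
            continue  # no eligible gene after the length filter
    return groups


def per_strain_codon_table(
    groups: dict[tuple[str, str], GeneGroup],
    n_repeats: int = DEFAULT_N_REPEATS,
    n_select: int = DEFAULT_N_SELECT,
    seed: int = 0,
) -> pd.DataFrame:
    """r_x / d^2 / KS summary for every strain with core and unique genes.

    ``groups`` maps (strain, class) -> GeneGroup, typically built from the
    CLOG labels; strains lacking either a core or a unique group are
    skipped.
    """
    rows = []
    for strain in sorted({s for s, _ in groups}):
        core = groups.get((strain, "core"))
        unique = groups.get((strain, "unique"))
        if core is None or unique is None:
            continue
        rng = np.random.default_rng([seed, zlib.crc32(strain.encode())])
        res = codon_usage_ratio(
            core, unique, n_repeats, n_select, rng, strain=strain
        )
        rows.append(
            {
                "strain": strain,
                "n_core_genes": len(core),
                "n_unique_genes": len(unique),
                "d2_core_core": res.d_core_core.d_sq,
                "d2_core_unique": res.d_core_unique.d_sq,
                "r_x": res.r_x,
                "ks_statistic": res.ks_statistic,
                "ks_p": res.ks_p,
            }
        )
    return pd.DataFrame(rows)
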