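"""EC-number annotation of CLOGs and metabolic presence/absence summaries.

A CLOG is *metabolic* if at least one member gene maps to an Enzyme
Commission (EC) number; the gene-to-EC mapping is a plain two-column input
file, keeping the pipeline deterministic and offline.  A CLOG whose members
carry different EC numbers keeps them all, unless one number is merely an
incomplete prefix form of another (e.g. ``3.7.-.-`` next to ``3.7.4.21``),
in which case only the more specific number is retained.  Enzyme complexes
spread over several CLOGs need no special handling: the complex's EC number
simply annotates each participating CLOG.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .clustering import CLOGSet
from .pangenome import clog_class

__all__ = [
    "ECAnnotation",
    "read_gene2ec",
    "collapse_incomplete",
    "assign_ec_to_clogs",
    "metabolic_summary",
    "shared_ec_matrix",
    "cluster_ec_matrix",
    "enzyme_presence_table",
]

_EC_RE = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")


def _check_ec(ec: str, context: str = "") -> None:
    if not _EC_RE.match(ec):
        raise ValueError(f"malformed EC number {ec!r}{context}")


def is_incomplete_form(partial: str, full: str) -> bool:
    """True if ``partial`` is an incomplete prefix form of ``full``.

    Field-wise: every field of ``partial`` equals the corresponding field of
    ``full`` or is ``-``; the two numbers must differ.
    """
    if partial == full:
        return False
    pf, ff = partial.split("."), full.split(".")
    return all(p == f or p == "-" for p, f in zip(pf, ff))


def collapse_incomplete(ecs: set[str]) -> frozenset[str]:
    """Drop every EC that is an incomplete form of another in the set.

    Idempotent: the survivors contain no prefix pair by construction.
    """
    return frozenset(
        ec
        for ec in ecs
        if not any(is_incomplete_form(ec, other) for other in ecs)
    )


def read_gene2ec(path: str) -> dict[str, set[str]]:
    """Parse a two-column (gene id, EC) TSV; one row per gene-EC pair."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            gene, ec = fields
            _check_ec(ec, context=f" at {path}:{lineno}")
            mapping.setdefault(gene, set()).add(ec)
    return mapping


@dataclass
class ECAnnotation:
    """Per-CLOG EC sets (after incomplete-form collapse)."""

    ec_sets: dict[str, frozenset[str]]  # clog id -> collapsed ECs
    gene2ec: dict[str, set[str]]

    def is_metabolic(self, clog_id: str) -> bool:
        return bool(self.ec_sets.get(clog_id))

    def distinct_ecs(self) -> set[str]:
        return set().union(*self.ec_sets.values()) if self.ec_sets else set()


def assign_ec_to_clogs(
    clogs: CLOGSet, gene2ec: dict[str, set[str]]
) -> ECAnnotation:
    """Annotate each CLOG with the collapsed union of its members' ECs.

    Genes absent from the mapping contribute nothing; a CLOG with no mapped
    member gets an empty set and is non-metabolic.
    """
    for gene, ecs in gene2ec.items():
        for ec in ecs:
            _check_ec(ec, context=f" for gene {gene!r}")
    ec_sets = {}
    for c in clogs:
        union: set[str] = set()
        for g in c.members:
            union |= gene2ec.get(g, set())
        ec_sets[c.clog_id] = collapse_incomplete(union)
    return ECAnnotation(ec_sets=ec_sets, gene2ec=gene2ec)


def metabolic_summary(annotation: ECAnnotation, labels) -> dict:
    """Counts of metabolic CLOGs, distinct ECs and per-class fractions.

    ``labels`` is the PangenomeLabels of the same CLOGSet.
    """
    label_of = labels.label_of()
    metabolic = [c for c, ecs in annotation.ec_sets.items() if ecs]
    per_class_total = Counter(label_of.values())
    per_class_metabolic = Counter(label_of[c] for c in metabolic)
    fractions = {
        cls: (per_class_metabolic[cls] / per_class_total[cls])
        if per_class_total[cls]
        else 0.0
        for cls in ("core", "shared", "unique")
    }
    return {
        "n_clogs": len(annotation.ec_sets),
        "n_metabolic_clogs": len(metabolic),
        "n_distinct_ecs": len(annotation.distinct_ecs()),
        "n_multi_ec_clogs": sum(
            1 for ecs in annotation.ec_sets.values() if len(ecs) > 1
        ),
        "metabolic_fraction": fractions,
    }


def shared_ec_matrix(
    annotation: ECAnnotation,
    clogs: CLOGSet,
    scope: str = "shared",
) -> pd.DataFrame:
    """Binary EC-by-strain presence matrix.

    An EC is present in a strain iff some CLOG containing that strain
    carries the EC.  With ``scope='shared'`` rows are restricted to ECs
    present in more than one but not all strains (row sums in 2..K-1);
    ``scope='all'`` keeps every EC.
    """
    if scope not in ("shared", "all"):
        raise ValueError(f"unknown scope {scope!r}")
    strains = list(clogs.strains)
    k = len(strains)
    presence: dict[str, set[str]] = {}
    for c in clogs:
        for ec in annotation.ec_sets.get(c.clog_id, ()):
            presence.setdefault(ec, set()).update(c.strains)
    rows = sorted(presence)
    if scope == "shared":
        rows = [ec for ec in rows if 2 <= len(presence[ec]) <= k - 1]
    m = pd.DataFrame(0, index=rows, columns=strains, dtype=int)
    for ec in rows:
        for s in presence[ec]:
            m.loc[ec, s] = 1
    m.index.name = "ec"
    return m


@dataclass
class ClusteredMatrix:
    """Row/column leaf orderings of a hierarchically clustered binary matrix."""

    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray | None

    def reorder(self, matrix: pd.DataFrame) -> pd.DataFrame:
        return matrix.loc[self.row_order, self.col_order]


def cluster_ec_matrix(matrix: pd.DataFrame) -> ClusteredMatrix:
    """Cluster rows and columns under Hamming distance, average linkage.

    The Hamming distance between two binary rows is the fraction of strain
    columns on which they disagree.  Returns the dendrogram leaf orderings
    used to render heatmaps; columns are clustered the same way whenever
    there are >= 3 of them.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    x = matrix.to_numpy(dtype=float)
    row_link = hierarchy.linkage(pdist(x, metric="hamming"), method="average")
    row_order = [matrix.index[i] for i in hierarchy.leaves_list(row_link)]
    if matrix.shape[1] >= 3:
        col_link = hierarchy.linkage(pdist(x.T, metric="hamming"), method="average")
        col_order = [matrix.columns[i] for i in hierarchy.leaves_list(col_link)]
    else:
        col_link = None
        col_order = list(matrix.columns)
    return ClusteredMatrix(
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_link,
        col_linkage=col_link,
    )


def enzyme_presence_table(
    annotation: ECAnnotation,
    clogs: CLOGSet,
    ec_list: list[str],
) -> pd.DataFrame:
    """CLOG multiplicity of selected enzymes per strain.

    Entry (strain, EC) counts the distinct CLOGs that carry the EC and
    contain the strain — the multiplicity rendered as dots in per-enzyme
    presence tables (0 = absent, 2 = two distinct carrying CLOGs, ...).
    Unknown ECs are reported in the returned frame's ``attrs['unknown_ecs']``
    rather than raising.
    """
    if not ec_list:
        raise ValueError("ec_list must be non-empty")
    known = annotation.distinct_ecs()
    unknown = [ec for ec in ec_list if ec not in known]
    strains = list(clogs.strains)
    table = pd.DataFrame(0, index=strains, columns=ec_list, dtype=int)
    for c in clogs:
        for ec in annotation.ec_sets.get(c.clog_id, ()):
            if ec in table.columns:
                for s in c.strains:
                    table.loc[s, ec] += 1
    table.index.name = "strain"
    table.attrs["unknown_ecs"] = unknown
    return table
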