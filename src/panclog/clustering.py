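"""Clusters of likely ortholog genes (CLOGs).

Genes are partitioned in three stages:

1. **Bidirectional hit rate (BHR).**  For a gene pair (a, b) with surviving
   directed scores in both directions,

       BHR(a, b) = (S(a,b) / best(b, strain(a))) * (S(b,a) / best(a, strain(b)))

   where ``best(b, A)`` is the best surviving score of b against any gene of
   strain A.  BHR is 1 exactly for mutual best hits in both directions and
   lower otherwise.  Within-genome pairs are clamped to 0.95 so that
   cross-genome orthologs are favoured while recent duplicates can still
   qualify.

2. **Pre-clustering.**  Pairs with BHR >= 0.95 are putative orthologs;
   pre-clusters are the connected components of that subgraph.

3. **UPGMA refinement.**  Each pre-cluster is re-clustered agglomeratively:
   repeatedly merge the entity pair with the highest inter-entity BHR while
   that maximum is >= 0.75, recomputing the merged entity's BHR to every
   other entity as the size-weighted average

       BHR(X, C) = (|A| BHR(A,C) + |B| BHR(B,C)) / (|A| + |B|),  X = A u B.

   Pairs with no surviving hit contribute BHR 0 to the average.  This splits
   pre-clusters in which two genes are only weakly connected through a third.

The final entities over all pre-clusters form the CLOG partition: every gene
belongs to exactly one CLOG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import networkx as nx

from .model import Proteomes
from .scoring import DEFAULT_MIN_BITS, SimilarityTable, score_all_pairs

__all__ = [
    "BHRGraph",
    "CLOG",
    "CLOGSet",
    "compute_bhr",
    "precluster",
    "upgma_refine",
    "build_clogs",
]

DEFAULT_CAP_SAME_GENOME = 0.95
DEFAULT_ORTHOLOG_THRESHOLD = 0.95
DEFAULT_UPGMA_MIN = 0.75


class BHRGraph:
    """Undirected bidirectional-hit-rate values per gene pair.

    Edges exist only where both directed scores survived the bit-score
    floor; every absent pair is treated as BHR 0 downstream.
    """

    def __init__(
        self,
        edges: dict[tuple[str, str], float],
        strain_of: dict[str, str],
        cap_same_genome: float = DEFAULT_CAP_SAME_GENOME,
    ):
        self._edges: dict[tuple[str, str], float] = {}
        for (a, b), v in edges.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"BHR({a!r}, {b!r}) = {v} outside [0, 1]")
            self._edges[self._key(a, b)] = v
        self._strain_of = dict(strain_of)
        self.cap_same_genome = cap_same_genome

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def bhr(self, a: str, b: str) -> float:
        """BHR of a pair; 0 when either direction had no surviving hit."""
        return self._edges.get(self._key(a, b), 0.0)

    @property
    def edges(self) -> dict[tuple[str, str], float]:
        return dict(self._edges)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted(self._strain_of))

    def strain_of(self, gene: str) -> str:
        return self._strain_of[gene]


@dataclass(frozen=True)
class CLOG:
    """One cluster of likely ortholog genes."""

    clog_id: str
    members: frozenset[str]
    strains: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("CLOG must be non-empty")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def n_strains(self) -> int:
        return len(self.strains)


class CLOGSet:
    """A partition of the gene universe into CLOGs."""

    def __init__(
        self,
        clogs: Iterable[CLOG],
        strain_of: dict[str, str],
        parameters: dict | None = None,
        strains: Iterable[str] | None = None,
    ):
        self.clogs: tuple[CLOG, ...] = tuple(clogs)
        self.strain_of = dict(strain_of)
        self.parameters = dict(parameters or {})
        seen: set[str] = set()
        for c in self.clogs:
            overlap = seen & c.members
            if overlap:
                raise ValueError(f"gene(s) {sorted(overlap)} in more than one CLOG")
            seen |= c.members
            derived = frozenset(self.strain_of[g] for g in c.members)
            if derived != c.strains:
                raise ValueError(f"CLOG {c.clog_id}: strain set inconsistent")
        missing = set(self.strain_of) - seen
        if missing:
            raise ValueError(f"gene(s) {sorted(missing)[:5]} assigned to no CLOG")
        derived = set(self.strain_of.values())
        if strains is None:
            self.strains: tuple[str, ...] = tuple(sorted(derived))
        else:
            declared = tuple(strains)
            if not derived <= set(declared):
                raise ValueError("declared strain list misses strains with genes")
            self.strains = declared

    def __len__(self) -> int:
        return len(self.clogs)

    def __iter__(self):
        return iter(self.clogs)

    @property
    def n_genes(self) -> int:
        return len(self.strain_of)

    def membership(self) -> dict[str, str]:
        """gene id -> clog id."""
        return {g: c.clog_id for c in self.clogs for g in c.members}


def compute_bhr(
    table: SimilarityTable,
    cap_same_genome: float = DEFAULT_CAP_SAME_GENOME,
) -> BHRGraph:
    """Bidirectional hit rates for every pair with hits in both directions."""
    edges: dict[tuple[str, str], float] = {}
    entries = table.entries
    for (a, b), s_ab in entries.items():
        if a >= b:
            continue  # handle each unordered pair once
        s_ba = entries.get((b, a))
        if s_ba is None:
            continue
        strain_a = table.strain_of(a)
        strain_b = table.strain_of(b)
        bhr = (s_ab / table.best_against(b, strain_a)) * (
            s_ba / table.best_against(a, strain_b)
        )
        if strain_a == strain_b:
            bhr = min(bhr, cap_same_genome)
        edges[(a, b)] = bhr
    return BHRGraph(
        edges,
        {g: table.strain_of(g) for g in table.genes},
        cap_same_genome=cap_same_genome,
    )


def precluster(
    graph: BHRGraph,
    ortholog_threshold: float = DEFAULT_ORTHOLOG_THRESHOLD,
) -> list[set[str]]:
    """Connected components of the BHR >= threshold subgraph.

    Genes with no qualifying edge form singleton components.  Components are
    returned sorted by their smallest gene id for determinism.
    """
    g = nx.Graph()
    g.add_nodes_from(graph.genes)
    for (a, b), v in graph.edges.items():
        if v >= ortholog_threshold:
            g.add_edge(a, b)
    components = [set(c) for c in nx.connected_components(g)]
    return sorted(components, key=lambda c: min(c))


def upgma_refine(
    cluster: Iterable[str],
    graph: BHRGraph,
    min_bhr: float = DEFAULT_UPGMA_MIN,
) -> list[frozenset[str]]:
    """Agglomerative (UPGMA-style) refinement of one pre-cluster.

    Seeds with singleton entities and merges the highest-BHR entity pair
    while that maximum is >= ``min_bhr``, applying the size-weighted average
    update to all other entities.  Ties on the maximal BHR are broken toward
    the merge whose combined sorted member tuple is lexicographically
    smallest.  Returns the final entities.
    """
    entities: list[tuple[str, ...]] = [(g,) for g in sorted(set(cluster))]
    if len(entities) <= 1:
        return [frozenset(e) for e in entities]
    # similarity between current entities, keyed by entity list indices
    sim: dict[tuple[int, int], float] = {}
    for i in range(len(entities)):
        for j in range(i + 1, len(entities)):
            sim[(i, j)] = graph.bhr(entities[i][0], entities[j][0])
    sizes = {i: 1 for i in range(len(entities))}
    alive = set(range(len(entities)))
    members: dict[int, tuple[str, ...]] = dict(enumerate(entities))
    next_id = len(entities)

    def pair_key(i: int, j: int) -> tuple[str, ...]:
        return tuple(sorted(members[i] + members[j]))

    while len(alive) > 1:
        best_pair: tuple[int, int] | None = None
        best_val = -1.0
        for (i, j), v in sim.items():
            if v > best_val or (
                v == best_val
                and best_pair is not None
                and pair_key(i, j) < pair_key(*best_pair)
            ):
                best_val = v
                best_pair = (i, j)
        if best_val < min_bhr or best_pair is None:
            break
        i, j = best_pair
        new = next_id
        next_id += 1
        members[new] = tuple(sorted(members[i] + members[j]))
        sizes[new] = sizes[i] + sizes[j]
        alive.discard(i)
        alive.discard(j)
        for k in alive:
            s_ik = sim.pop((min(i, k), max(i, k)))
            s_jk = sim.pop((min(j, k), max(j, k)))
            sim[(k, new)] = (sizes[i] * s_ik + sizes[j] * s_jk) / (
                sizes[i] + sizes[j]
            )
        sim.pop((i, j), None)
        alive.add(new)
    return sorted((frozenset(members[i]) for i in alive), key=min)


def build_clogs(
    proteomes: Proteomes,
    scorer: Callable[[str, str], float] | None = None,
    *,
    table: SimilarityTable | None = None,
    min_bits: float = DEFAULT_MIN_BITS,
    cap_same_genome: float = DEFAULT_CAP_SAME_GENOME,
    ortholog_threshold: float = DEFAULT_ORTHOLOG_THRESHOLD,
    upgma_min: float = DEFAULT_UPGMA_MIN,
) -> CLOGSet:
    """End-to-end CLOG construction.

    Composes all-vs-all scoring, BHR computation, >= threshold
    pre-clustering and per-pre-cluster UPGMA refinement into a partition of
    all genes.  A precomputed ``table`` (e.g. imported blast scores)
    bypasses the internal scorer.
    """
    if table is None:
        table = score_all_pairs(proteomes, scorer=scorer, min_bits=min_bits)
    graph = compute_bhr(table, cap_same_genome=cap_same_genome)
    clusters: list[frozenset[str]] = []
    for pre in precluster(graph, ortholog_threshold=ortholog_threshold):
        clusters.extend(upgma_refine(pre, graph, min_bhr=upgma_min))
    clusters.sort(key=min)
    strain_of = {g: graph.strain_of(g) for g in graph.genes}
    clogs = [
        CLOG(
            clog_id=f"CLOG{i + 1:05d}",
            members=c,
            strains=frozenset(strain_of[g] for g in c),
        )
        for i, c in enumerate(clusters)
    ]
    return CLOGSet(
        clogs,
        strain_of,
        parameters={
            "min_bits": min_bits,
            "cap_same_genome": cap_same_genome,
            "ortholog_threshold": ortholog_threshold,
            "upgma_min": upgma_min,
        },
    )
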