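"""Gene-sharing similarity, distances and neighbor-joining trees.

The similarity of two strains is the number of CLOGs containing both divided
by the number of CLOGs containing at least one of them (a Jaccard index over
CLOG memberships).  By default core CLOGs (identical across all strains) and
unique CLOGs (which would only add genome-size bias) are excluded before
computing the matrix.  Similarities become distances by subtracting every
entry from the maximal entry; the diagonal is then zeroed, and the matrix is
turned into a tree with classic neighbor joining, rooted at a designated
outgroup strain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .clustering import CLOGSet
from .pangenome import clog_class

__all__ = [
    "SharingMatrix",
    "sharing_similarity_matrix",
    "similarity_to_distance",
    "neighbor_joining_tree",
]

Mode = Literal["all_clogs", "exclude_core_and_unique"]


@dataclass
class SharingMatrix:
    """Symmetric strain-by-strain gene-sharing similarity in [0, 1]."""

    strains: tuple[str, ...]
    values: pd.DataFrame
    mode: Mode


def sharing_similarity_matrix(
    clogs: CLOGSet,
    mode: Mode = "exclude_core_and_unique",
) -> SharingMatrix:
    """Jaccard sharing similarity over the CLOG subset selected by ``mode``.

    S(i, j) = |CLOGs containing i and j| / |CLOGs containing i or j|.  A
    strain pair with an empty union scores 0; an entirely empty CLOG subset
    under the chosen mode is an error.
    """
    strains = list(clogs.strains)
    k = len(strains)
    if mode == "all_clogs":
        subset = list(clogs)
    elif mode == "exclude_core_and_unique":
        subset = [c for c in clogs if clog_class(c.n_strains, k) == "shared"]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not subset:
        raise ValueError(f"no CLOGs left under mode {mode!r}")
    member_sets = {s: set() for s in strains}
    for n, c in enumerate(subset):
        for s in c.strains:
            member_sets[s].add(n)
    m = np.zeros((k, k))
    for i, si in enumerate(strains):
        for j, sj in enumerate(strains):
            union = len(member_sets[si] | member_sets[sj])
            inter = len(member_sets[si] & member_sets[sj])
            m[i, j] = inter / union if union else 0.0
    return SharingMatrix(
        strains=tuple(strains),
        values=pd.DataFrame(m, index=strains, columns=strains),
        mode=mode,
    )


def similarity_to_distance(matrix: SharingMatrix) -> pd.DataFrame:
    """D = max(S) - S entrywise, with the diagonal zeroed afterwards.

    The raw transform does not guarantee a zero diagonal whenever
    self-similarity is below the maximal entry; neighbor joining requires
    one, so the diagonal is explicitly reset.
    """
    s = matrix.values.to_numpy()
    d = s.max() - s
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.values.index, columns=matrix.values.columns)


def neighbor_joining_tree(
    distances: pd.DataFrame,
    outgroup: str | None = None,
) -> TreeNode:
    """Classic neighbor joining (Saitou-Nei), optionally outgroup-rooted.

    Requires a symmetric, hollow, non-negative matrix over >= 3 strains.
    Negative branch lengths produced by NJ are clamped to zero with the
    difference transferred to the adjacent branch.  When ``outgroup`` is
    given, the root is inserted at the midpoint of the outgroup's pendant
    edge.  Returns a tree whose ``str()`` is newick with branch lengths.
    """
    arr = distances.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or arr.shape[0] < 3:
        raise ValueError("need a square matrix over >= 3 strains")
    if not np.allclose(arr, arr.T):
        raise ValueError("distance matrix must be symmetric")
    if (arr < 0).any():
        raise ValueError("distance matrix must be non-negative")
    dm = DistanceMatrix(arr, ids=list(distances.index))
    tree = nj(dm, neg_as_zero=True)
    if outgroup is not None:
        tip = tree.find(outgroup)
        if not tip.is_tip():
            raise ValueError(f"outgroup {outgroup!r} is not a leaf")
        half = (tip.length or 0.0) / 2.0
        tree = tree.root_at(outgroup, above=half, reset=True)
    return tree
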