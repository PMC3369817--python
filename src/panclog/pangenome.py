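"""Core/shared/unique partitioning, sharing counts and rarefaction curves.

A CLOG present in all K strains is *core*, in exactly one strain *unique*,
and otherwise *shared*.  Rarefaction curves estimate how the pan-genome
(union of CLOGs) grows and the core genome (intersection) shrinks as strains
are added in random order; medians and 0.1/0.9 quantiles are taken over the
sampled strain permutations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import CLOGSet

__all__ = [
    "PangenomeLabels",
    "RarefactionResult",
    "classify_clogs",
    "clog_size_histogram",
    "pairwise_shared_matrix",
    "rarefaction",
]

CLASSES = ("core", "shared", "unique")


def clog_class(n_strains: int, k_total: int) -> str:
    """Class of a CLOG from its strain count (pure function of n)."""
    if n_strains == k_total:
        return "core"
    if n_strains == 1:
        return "unique"
    return "shared"


@dataclass
class PangenomeLabels:
    """Per-CLOG core/shared/unique labels plus the standard summaries."""

    table: pd.DataFrame  # columns: clog_id, n_strains, label
    n_strains_total: int
    strain_count_hist: dict[int, int]  # n strains -> number of CLOGs
    per_strain_counts: pd.DataFrame  # strains x (core, shared, unique)

    def class_counts(self) -> dict[str, int]:
        counts = self.table["label"].value_counts().to_dict()
        return {c: int(counts.get(c, 0)) for c in CLASSES}

    def label_of(self) -> dict[str, str]:
        return dict(zip(self.table["clog_id"], self.table["label"]))


def classify_clogs(clogs: CLOGSet) -> PangenomeLabels:
    """Label every CLOG and build the strain-count and per-strain summaries."""
    k = len(clogs.strains)
    rows = []
    hist: Counter[int] = Counter()
    per_strain = {s: {c: 0 for c in CLASSES} for s in clogs.strains}
    for c in clogs:
        label = clog_class(c.n_strains, k)
        rows.append((c.clog_id, c.n_strains, label))
        hist[c.n_strains] += 1
        for s in c.strains:
            per_strain[s][label] += 1
    table = pd.DataFrame(rows, columns=["clog_id", "n_strains", "label"])
    per_strain_df = pd.DataFrame.from_dict(per_strain, orient="index")[list(CLASSES)]
    per_strain_df.index.name = "strain"
    return PangenomeLabels(
        table=table,
        n_strains_total=k,
        strain_count_hist=dict(sorted(hist.items())),
        per_strain_counts=per_strain_df,
    )


def clog_size_histogram(clogs: CLOGSet) -> dict[int, int]:
    """Histogram of genes per CLOG; sizes times counts sum to total genes."""
    hist: Counter[int] = Counter(c.size for c in clogs)
    return dict(sorted(hist.items()))


def pairwise_shared_matrix(clogs: CLOGSet) -> pd.DataFrame:
    """Symmetric strain-by-strain CLOG sharing counts.

    Off-diagonal (i, j): CLOGs containing at least one gene of both strains;
    diagonal (i, i): CLOGs containing at least one gene of strain i.
    """
    strains = list(clogs.strains)
    idx = {s: i for i, s in enumerate(strains)}
    m = np.zeros((len(strains), len(strains)), dtype=int)
    for c in clogs:
        present = sorted(idx[s] for s in c.strains)
        for a_pos, i in enumerate(present):
            m[i, i] += 1
            for j in present[a_pos + 1 :]:
                m[i, j] += 1
                m[j, i] += 1
    return pd.DataFrame(m, index=strains, columns=strains)


@dataclass
class RarefactionResult:
    """Pan/core curves over sampled strain orders.

    ``core_counts``/``pan_counts`` hold the raw per-iteration trajectories
    (n_iterations x K) backing the summary table.
    """

    table: pd.DataFrame
    core_counts: np.ndarray
    pan_counts: np.ndarray
    n_iterations: int
    seed: int


def rarefaction(
    clogs: CLOGSet,
    n_iterations: int = 1000,
    seed: int = 0,
) -> RarefactionResult:
    """Estimate pan- and core-genome sizes as strains are added in random order.

    For each of ``n_iterations`` uniformly random strain permutations and
    each prefix length n, core(n) counts CLOGs present in *all* of the first
    n strains and pan(n) counts CLOGs present in *at least one*.  The summary
    table reports the median and the 0.1/0.9 quantiles (linear interpolation
    between order statistics) across iterations.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    strains = list(clogs.strains)
    k = len(strains)
    idx = {s: i for i, s in enumerate(strains)}
    presence = np.zeros((len(clogs.clogs), k), dtype=bool)
    for row, c in enumerate(clogs):
        for s in c.strains:
            presence[row, idx[s]] = True

    rng = np.random.default_rng(seed)
    core_counts = np.empty((n_iterations, k), dtype=np.int64)
    pan_counts = np.empty((n_iterations, k), dtype=np.int64)
    for it in range(n_iterations):
        perm = rng.permutation(k)
        p = presence[:, perm]
        pan_counts[it] = np.logical_or.accumulate(p, axis=1).sum(axis=0)
        core_counts[it] = np.logical_and.accumulate(p, axis=1).sum(axis=0)

    def q(a: np.ndarray, frac: float) -> np.ndarray:
        return np.quantile(a, frac, axis=0, method="linear")

    table = pd.DataFrame(
        {
            "n": np.arange(1, k + 1),
            "core_median": np.median(core_counts, axis=0),
            "core_q10": q(core_counts, 0.1),
            "core_q90": q(core_counts, 0.9),
            "pan_median": np.median(pan_counts, axis=0),
            "pan_q10": q(pan_counts, 0.1),
            "pan_q90": q(pan_counts, 0.9),
        }
    )
    return RarefactionResult(
        table=table,
        core_counts=core_counts,
        pan_counts=pan_counts,
        n_iterations=n_iterations,
        seed=seed,
    )
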