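"""Shared fixtures: planted pangenomes built once per session."""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pytest

from panclog import build_clogs, codon
from panclog import simulate as sim


@dataclass
class PlantedFixture:
    pangenome: sim.PlantedPangenome
    records: list[sim.GeneRecord]
    proteomes: dict
    truth: dict[str, str]


@pytest.fixture(scope="session")
def fixture5() -> PlantedFixture:
    """5-strain planted pangenome: 10 core, 20 shared, 6 unique per strain,
    divergence 0.1 — the standard clustering test bed."""
    pg = sim.generate_pangenome(5, 10, 20, 6, 0.1, seed=1)
    records = sim.synthesize_gene_sequences(pg)
    return PlantedFixture(
        pangenome=pg,
        records=records,
        proteomes=sim.as_proteomes(records),
        truth=sim.truth_families(records),
    )


@pytest.fixture(scope="session")
def clogs5(fixture5):
    """CLOGs built from the 5-strain fixture (the slow step, shared)."""
    return build_clogs(fixture5.proteomes)


@pytest.fixture(scope="session")
def codon_fixture():
    """3-strain pangenome with planted per-strain core codon bias and a
    divergent unique-gene bias; groups keyed by (strain, class)."""
    pg = sim.generate_pangenome(3, 150, 0, 120, 0.1, seed=2)
    records = sim.synthesize_gene_sequences(pg)
    cds: dict[tuple[str, str], dict[str, str]] = defaultdict(dict)
    for r in records:
        cds[(r.strain, r.family_class)][r.gene_id] = r.cds
    groups = {
        key: codon.GeneGroup.from_cds(f"{key[0]}/{key[1]}", mapping)
        for key, mapping in cds.items()
    }
    return pg, groups


def make_null_groups(seed: int, n_genes: int = 800, length: int = 60):
    """Two gene groups synthesized from one shared codon-usage table.

    Group sizes far exceed the 100-gene selection so that within-group and
    cross-group selections are comparably independent.
    """
    rng = np.random.default_rng([seed, 101])
    bias = sim.make_codon_bias_table(rng)
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    groups = []
    for tag in ("a", "b"):
        cds_map = {}
        for j in range(n_genes):
            protein = "".join(rng.choice(aa, size=length))
            cds_map[f"{tag}{j:04d}"] = sim.synthesize_cds(protein, bias, rng)
        groups.append(codon.GeneGroup.from_cds(tag, cds_map))
    return groups[0], groups[1]
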