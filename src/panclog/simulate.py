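"""Synthetic pangenome generator with planted ortholog families.

Every downstream stage of the pipeline (similarity scoring, CLOG clustering,
rarefaction, codon usage, trees, EC summaries) is testable against the planted
truth produced here, with no external data.

The generator plants three classes of gene families mirroring the empirical
core/shared/unique trichotomy of bacterial pan-genomes:

* **core** families have one member (or more, with paralogs) in every strain;
* **shared** families occupy a uniformly drawn subset of 2..K-1 strains;
* **unique** families occupy exactly one strain.

Family members diverge from a common random ancestor protein by i.i.d.
per-site substitution; at moderate divergence this guarantees that family
members are mutual best hits under local alignment, which the clustering
stages rely on.  Coding sequences are back-translated from the proteins using
per-strain synonymous-codon preference tables for core/shared families and a
single distinct preference table for unique-family genes, emulating the
atypical codon usage of strain-specific genes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from ._codons import (
    AA_TO_CODON_IDX,
    AMINO_ACIDS,
    SENSE_CODONS,
)
from .model import Gene, Proteomes

__all__ = [
    "PlantedFamily",
    "PlantedPangenome",
    "GeneRecord",
    "generate_pangenome",
    "make_codon_bias_table",
    "synthesize_cds",
    "synthesize_gene_sequences",
    "write_fixtures",
    "as_proteomes",
    "truth_families",
]

_CLASSES = ("core", "shared", "unique")


@dataclass(frozen=True)
class PlantedFamily:
    """A planted ortholog family.

    ``copies_per_strain`` maps each member strain to the number of gene
    copies it carries (>1 plants within-genome paralogs).
    """

    family_id: str
    family_class: str
    member_strains: tuple[str, ...]
    copies_per_strain: dict[str, int]
    ancestor_protein: str

    def __post_init__(self) -> None:
        if self.family_class not in _CLASSES:
            raise ValueError(f"unknown family class {self.family_class!r}")
        if len(self.ancestor_protein) < 50:
            raise ValueError("ancestor proteins must be >= 50 aa")
        if self.family_class == "unique" and len(self.member_strains) != 1:
            raise ValueError("unique families must occupy exactly one strain")
        if any(c < 1 for c in self.copies_per_strain.values()):
            raise ValueError("copies_per_strain must be positive")

    @property
    def n_genes(self) -> int:
        return sum(self.copies_per_strain[s] for s in self.member_strains)


@dataclass
class PlantedPangenome:
    """A full planted pangenome configuration.

    ``codon_bias`` holds one within-amino-acid codon weight vector (length
    61, normalised per synonym group) per strain, used for core and shared
    genes; ``unique_codon_bias`` is the separate table used for all
    unique-family genes.
    """

    strains: list[str]
    families: list[PlantedFamily]
    divergence: float
    codon_bias: dict[str, np.ndarray]
    unique_codon_bias: np.ndarray
    seed: int

    @property
    def n_genes(self) -> int:
        return sum(f.n_genes for f in self.families)

    def class_counts(self) -> dict[str, int]:
        out = {c: 0 for c in _CLASSES}
        for f in self.families:
            out[f.family_class] += 1
        return out


@dataclass(frozen=True)
class GeneRecord:
    """A generated gene together with its planted truth labels."""

    gene_id: str
    strain: str
    family_id: str
    family_class: str
    protein: str
    cds: str


def make_codon_bias_table(rng: np.random.Generator, strength: float = 0.85) -> np.ndarray:
    """Draw a synonymous-codon preference table.

    For each amino acid with k synonymous codons, one codon (chosen at
    random) receives weight ``strength`` and the remaining k-1 share
    ``1 - strength`` equally.  Returns a length-61 vector normalised within
    each synonym group.
    """
    if not 0.0 < strength <= 1.0:
        raise ValueError("strength must be in (0, 1]")
    w = np.zeros(len(SENSE_CODONS))
    for aa in AMINO_ACIDS:
        idx = AA_TO_CODON_IDX[aa]
        k = len(idx)
        if k == 1:
            w[idx] = 1.0
            continue
        pref = int(rng.integers(k))
        w[idx] = (1.0 - strength) / (k - 1)
        w[idx[pref]] = strength
    return w


def generate_pangenome(
    n_strains: int,
    n_core: int,
    n_shared: int,
    n_unique_per_strain: int,
    divergence: float,
    seed: int,
    *,
    length_range: tuple[int, int] = (60, 400),
    bias_strength: float = 0.85,
    paralog_fraction: float = 0.0,
    paralog_copies: int = 2,
) -> PlantedPangenome:
    """Plant a pangenome configuration (families, ancestors, codon biases).

    Parameters
    ----------
    n_strains
        Number of strains K (>= 2; the core/shared/unique trichotomy is
        undefined for a single strain).
    n_core, n_shared, n_unique_per_strain
        Family counts per class; shared-family member counts are drawn
        uniformly from 2..K-1 (requires K >= 3 when ``n_shared > 0``).
    divergence
        Expected per-site protein substitution fraction within a family,
        in [0, 0.5].
    length_range
        Inclusive ancestor length bounds in amino acids; the lower bound
        must stay >= 50 so no generated gene falls below the codon-usage
        length floor.
    paralog_fraction
        Fraction of core/shared families planted with ``paralog_copies``
        copies in one random member strain (exercises the same-genome
        handling of the clustering stage).
    """
    if n_strains < 2:
        raise ValueError("n_strains must be >= 2")
    if not 0.0 <= divergence <= 0.5:
        raise ValueError("divergence must be in [0, 0.5]")
    if n_shared > 0 and n_strains < 3:
        raise ValueError("shared families require n_strains >= 3")
    if length_range[0] < 50:
        raise ValueError("minimum gene length is 50 aa")

    rng = np.random.default_rng(seed)
    strains = [f"S{i + 1:02d}" for i in range(n_strains)]

    def ancestor() -> str:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        return "".join(
            AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=length)
        )

    families: list[PlantedFamily] = []
    counter = 0

    def new_family(cls: str, members: list[str]) -> None:
        nonlocal counter
        counter += 1
        copies = {s: 1 for s in members}
        if cls != "unique" and paralog_fraction > 0.0:
            if rng.random() < paralog_fraction:
                copies[members[int(rng.integers(len(members)))]] = paralog_copies
        families.append(
            PlantedFamily(
                family_id=f"F{counter:04d}",
                family_class=cls,
                member_strains=tuple(members),
                copies_per_strain=copies,
                ancestor_protein=ancestor(),
            )
        )

    for _ in range(n_core):
        new_family("core", list(strains))
    for _ in range(n_shared):
        m = int(rng.integers(2, n_strains))  # uniform on 2..K-1
        members = sorted(rng.choice(strains, size=m, replace=False).tolist())
        new_family("shared", members)
    for s in strains:
        for _ in range(n_unique_per_strain):
            new_family("unique", [s])

    codon_bias = {s: make_codon_bias_table(rng, bias_strength) for s in strains}
    unique_bias = make_codon_bias_table(rng, bias_strength)

    return PlantedPangenome(
        strains=strains,
        families=families,
        divergence=divergence,
        codon_bias=codon_bias,
        unique_codon_bias=unique_bias,
        seed=seed,
    )


def _protein_to_idx(protein: str) -> np.ndarray:
    return np.frombuffer(protein.encode(), dtype=np.uint8)


_AA_LOOKUP = np.full(128, -1, dtype=np.int64)
for _i, _a in enumerate(AMINO_ACIDS):
    _AA_LOOKUP[ord(_a)] = _i


def _mutate(protein: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability ``divergence`` to a uniformly
    chosen *different* residue (no indels)."""
    idx = _AA_LOOKUP[_protein_to_idx(protein)]
    mask = rng.random(idx.size) < divergence
    shift = rng.integers(1, len(AMINO_ACIDS), size=idx.size)
    mutated = np.where(mask, (idx + shift) % len(AMINO_ACIDS), idx)
    return "".join(AMINO_ACIDS[i] for i in mutated)


def synthesize_cds(protein: str, bias: np.ndarray, rng: np.random.Generator) -> str:
    """Back-translate ``protein`` sampling synonymous codons from ``bias``.

    ``bias`` is a length-61 weight vector; weights are renormalised within
    each amino acid's synonym group.  The returned CDS has length
    ``3 * len(protein)`` and carries no stop codon.
    """
    idx = _AA_LOOKUP[_protein_to_idx(protein)]
    if (idx < 0).any():
        bad = protein[int(np.argmax(idx < 0))]
        raise ValueError(f"cannot back-translate residue {bad!r}")
    codon_choice = np.empty(idx.size, dtype=np.int64)
    u = rng.random(idx.size)
    for aa_i in np.unique(idx):
        cods = AA_TO_CODON_IDX[AMINO_ACIDS[aa_i]]
        w = bias[cods]
        total = w.sum()
        if total <= 0:
            raise ValueError(f"bias table gives zero weight to all codons of {AMINO_ACIDS[aa_i]!r}")
        cum = np.cumsum(w / total)
        pos = idx == aa_i
        j = np.searchsorted(cum, u[pos], side="right")
        codon_choice[pos] = cods[np.minimum(j, len(cods) - 1)]
    return "".join(SENSE_CODONS[c] for c in codon_choice)


def synthesize_gene_sequences(pangenome: PlantedPangenome) -> list[GeneRecord]:
    """Generate every member gene's protein and CDS.

    Deterministic for a fixed pangenome (the sequence stream is derived from
    ``pangenome.seed``).  Paralogous copies within one strain are mutated
    from the strain's primary copy at a quarter of the family divergence, so
    recent duplicates remain near-identical.
    """
    rng = np.random.default_rng([pangenome.seed, 1])
    records: list[GeneRecord] = []
    for fam in pangenome.families:
        bias_of = (
            (lambda s: pangenome.unique_codon_bias)
            if fam.family_class == "unique"
            else (lambda s: pangenome.codon_bias[s])
        )
        for strain in fam.member_strains:
            primary = _mutate(fam.ancestor_protein, pangenome.divergence, rng)
            for copy in range(fam.copies_per_strain[strain]):
                if copy == 0:
                    protein = primary
                    gene_id = f"{fam.family_id}_{strain}"
                else:
                    protein = _mutate(primary, pangenome.divergence / 4.0, rng)
                    gene_id = f"{fam.family_id}_{strain}_c{copy + 1}"
                cds = synthesize_cds(protein, bias_of(strain), rng)
                records.append(
                    GeneRecord(
                        gene_id=gene_id,
                        strain=strain,
                        family_id=fam.family_id,
                        family_class=fam.family_class,
                        protein=protein,
                        cds=cds,
                    )
                )
    return records


def as_proteomes(records: list[GeneRecord]) -> Proteomes:
    """Group generated genes by strain as the scoring stage expects."""
    out: Proteomes = {}
    for r in records:
        out.setdefault(r.strain, []).append(
            Gene(id=r.gene_id, strain=r.strain, protein=r.protein, cds=r.cds)
        )
    return out


def truth_families(records: list[GeneRecord]) -> dict[str, str]:
    """gene id -> planted family id (the ground-truth partition)."""
    return {r.gene_id: r.family_id for r in records}


def write_fixtures(
    pangenome: PlantedPangenome,
    out_dir: str,
    records: list[GeneRecord] | None = None,
) -> dict[str, str]:
    """Write per-strain protein/CDS FASTA files plus a truth TSV.

    FASTA headers follow the ``gene_id|strain_id`` dialect.  A TAA stop codon
    is appended to each written CDS record (and stripped again by the
    readers); stop codons are excluded from all analyses.  Returns a mapping
    of logical names to file paths.
    """
    if records is None:
        records = synthesize_gene_sequences(pangenome)
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}
    by_strain: dict[str, list[GeneRecord]] = {s: [] for s in pangenome.strains}
    for r in records:
        by_strain[r.strain].append(r)
    for strain in pangenome.strains:
        faa = os.path.join(out_dir, f"{strain}.faa")
        fna = os.path.join(out_dir, f"{strain}.fna")
        with open(faa, "w") as fh:
            for r in by_strain[strain]:
                fh.write(f">{r.gene_id}|{r.strain}\n{r.protein}\n")
        with open(fna, "w") as fh:
            for r in by_strain[strain]:
                fh.write(f">{r.gene_id}|{r.strain}\n{r.cds}TAA\n")
        paths[f"{strain}.faa"] = faa
        paths[f"{strain}.fna"] = fna
    truth = os.path.join(out_dir, "truth.tsv")
    with open(truth, "w") as fh:
        fh.write("gene_id\tstrain\tfamily_id\tclass\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.strain}\t{r.family_id}\t{r.family_class}\n")
    paths["truth.tsv"] = truth
    return paths
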