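"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Gene:
    """One protein-coding gene.

    Parameters
    ----------
    id
        Globally unique gene identifier. Must not contain the reserved
        delimiters ``|`` (FASTA header), ``~`` (multi-gene cell) or ``#``
        (EC summary).
    strain
        Identifier of the strain (genome) the gene belongs to.
    protein
        Amino-acid sequence (one-letter codes).
    cds
        Optional in-frame coding sequence, stop codon already stripped.
    """

    id: str
    strain: str
    protein: str
    cds: str | None = None

    def __post_init__(self) -> None:
        for bad in "|~#":
            if bad in self.id:
                raise ValueError(
                    f"gene id {self.id!r} contains reserved character {bad!r}"
                )


#: Mapping strain id -> list of genes of that strain.
Proteomes = dict[str, list[Gene]]


def flatten(proteomes: Proteomes) -> list[Gene]:
    """All genes of all strains, in deterministic (strain, id) order."""
    return [
        g
        for strain in sorted(proteomes)
        for g in sorted(proteomes[strain], key=lambda g: g.id)
    ]


def strain_map(proteomes: Proteomes) -> dict[str, str]:
    """gene id -> strain id; raises on duplicate gene ids."""
    out: dict[str, str] = {}
    for strain, genes in proteomes.items():
        for g in genes:
            if g.id in out:
                raise ValueError(f"duplicate gene id: {g.id!r}")
            out[g.id] = strain
    return out
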