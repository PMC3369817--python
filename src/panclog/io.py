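"""Readers and writers for the pipeline's file formats.

FASTA headers follow the ``gene_id|strain_id`` dialect.  The CLOG table is
tab-separated with one line per CLOG and one column per strain: multiple
genes of one strain are joined by ``~``, per-gene EC numbers are appended in
square brackets (``;``-separated), and the final column summarises the
CLOG's collapsed EC numbers with their frequency of appearance, ``#``
-separated.  The table round-trips byte-identically through
``read_clog_table`` / ``write_clog_table``.
"""

from __future__ import annotations

import os
import re
from typing import Iterable

from Bio import SeqIO

from ._codons import STOP_CODONS
from .clustering import CLOG, CLOGSet
from .metabolism import ECAnnotation, assign_ec_to_clogs
from .model import Gene, Proteomes

__all__ = [
    "read_proteomes",
    "read_cds_fasta",
    "attach_cds",
    "write_clog_table",
    "read_clog_table",
    "write_tsv_matrix",
]


def _parse_header(description: str, path: str) -> tuple[str, str]:
    name = description.split()[0]
    if "|" not in name:
        raise ValueError(
            f"{path}: header {name!r} does not follow the 'gene_id|strain_id' dialect"
        )
    gene_id, strain = name.split("|", 1)
    if not gene_id or not strain:
        raise ValueError(f"{path}: empty gene or strain id in header {name!r}")
    return gene_id, strain


def read_proteomes(paths: Iterable[str]) -> Proteomes:
    """Read per-strain protein FASTA files into a gene universe.

    Gene ids must be globally unique across all files; records carry their
    strain in the header (``gene_id|strain_id``).
    """
    proteomes: Proteomes = {}
    seen: set[str] = set()
    for path in paths:
        if not os.path.exists(path):
            raise FileNotFoundError(f"no such FASTA file: {path}")
        n_records = 0
        for rec in SeqIO.parse(path, "fasta"):
            gene_id, strain = _parse_header(rec.description, path)
            seq = str(rec.seq).upper()
            if not seq:
                raise ValueError(f"{path}: empty sequence for gene {gene_id!r}")
            if gene_id in seen:
                raise ValueError(f"duplicate gene id {gene_id!r} (in {path})")
            seen.add(gene_id)
            proteomes.setdefault(strain, []).append(
                Gene(id=gene_id, strain=strain, protein=seq)
            )
            n_records += 1
        if n_records == 0:
            raise ValueError(f"{path}: no FASTA records")
    return proteomes


def _strip_stop(cds: str) -> str:
    if len(cds) >= 3 and cds[-3:] in STOP_CODONS:
        return cds[:-3]
    return cds


def read_cds_fasta(paths: Iterable[str]) -> dict[str, str]:
    """Read CDS FASTA files keyed by gene id; trailing stop codons stripped."""
    out: dict[str, str] = {}
    for path in paths:
        if not os.path.exists(path):
            raise FileNotFoundError(f"no such FASTA file: {path}")
        for rec in SeqIO.parse(path, "fasta"):
            gene_id, _strain = _parse_header(rec.description, path)
            if gene_id in out:
                raise ValueError(f"duplicate gene id {gene_id!r} (in {path})")
            out[gene_id] = _strip_stop(str(rec.seq).upper())
    return out


def attach_cds(proteomes: Proteomes, cds: dict[str, str]) -> Proteomes:
    """Return proteomes with CDS attached where available."""
    return {
        strain: [
            Gene(id=g.id, strain=g.strain, protein=g.protein, cds=cds.get(g.id))
            for g in genes
        ]
        for strain, genes in proteomes.items()
    }


_GENE_EC_RE = re.compile(r"^(?P<gene>[^\[\]]+)(\[(?P<ecs>[^\[\]]*)\])?$")


def _format_gene(gene: str, gene2ec: dict[str, set[str]] | None) -> str:
    ecs = sorted(gene2ec.get(gene, ())) if gene2ec else []
    return f"{gene}[{';'.join(ecs)}]" if ecs else gene


def write_clog_table(
    clogs: CLOGSet,
    path: str,
    annotation: ECAnnotation | None = None,
) -> None:
    """Write the CLOG table in the tilde/hash dialect described above."""
    strains = list(clogs.strains)
    gene2ec = annotation.gene2ec if annotation else None
    with open(path, "w") as fh:
        fh.write("clog_id\t" + "\t".join(strains) + "\tEC_summary\n")
        for c in sorted(clogs, key=lambda c: c.clog_id):
            by_strain: dict[str, list[str]] = {s: [] for s in strains}
            for g in sorted(c.members):
                by_strain[clogs.strain_of[g]].append(_format_gene(g, gene2ec))
            cells = ["~".join(by_strain[s]) if by_strain[s] else "-" for s in strains]
            if annotation and annotation.ec_sets.get(c.clog_id):
                freq = {
                    ec: sum(
                        1
                        for g in c.members
                        if gene2ec and ec in gene2ec.get(g, ())
                    )
                    for ec in sorted(annotation.ec_sets[c.clog_id])
                }
                summary = "#".join(f"{ec}({n})" for ec, n in freq.items())
            else:
                summary = "-"
            fh.write(f"{c.clog_id}\t" + "\t".join(cells) + f"\t{summary}\n")


def read_clog_table(path: str) -> tuple[CLOGSet, dict[str, set[str]]]:
    """Read a CLOG table back into a CLOGSet plus the per-gene EC mapping."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[0] != "clog_id" or header[-1] != "EC_summary":
            raise ValueError(f"{path}: not a CLOG table (bad header)")
        strains = header[1:-1]
        clog_list: list[CLOG] = []
        strain_of: dict[str, str] = {}
        gene2ec: dict[str, set[str]] = {}
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}"
                )
            clog_id = fields[0]
            members: set[str] = set()
            member_strains: set[str] = set()
            for strain, cell in zip(strains, fields[1:-1]):
                if cell == "-":
                    continue
                for token in cell.split("~"):
                    m = _GENE_EC_RE.match(token)
                    if not m:
                        raise ValueError(f"{path}:{lineno}: bad gene token {token!r}")
                    gene = m.group("gene")
                    members.add(gene)
                    member_strains.add(strain)
                    strain_of[gene] = strain
                    if m.group("ecs"):
                        gene2ec[gene] = set(m.group("ecs").split(";"))
            clog_list.append(
                CLOG(
                    clog_id=clog_id,
                    members=frozenset(members),
                    strains=frozenset(member_strains),
                )
            )
    return CLOGSet(clog_list, strain_of, strains=strains), gene2ec


def rebuild_annotation(
    clogs: CLOGSet, gene2ec: dict[str, set[str]]
) -> ECAnnotation:
    """Re-derive the per-CLOG annotation from a round-tripped gene map."""
    return assign_ec_to_clogs(clogs, gene2ec)


def write_tsv_matrix(df, path: str) -> None:
    """Write a labelled matrix or table as TSV (row labels in first column)."""
    df.to_csv(path, sep="\t")
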