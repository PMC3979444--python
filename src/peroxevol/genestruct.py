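"""Intron position/phase extraction and homology mapping on a protein MSA.

An intron's position within the coding sequence is summarized by its phase —
0 if it falls between two codons, 1 if between the first and second codon
nucleotides, 2 if between the second and third — and by the codon it
interrupts.  Introns are projected onto the columns of the protein alignment
(phase-0 introns anchor to the residue immediately following the intron, a
fixed convention of this package), clustered into homologous positions with
a small sliding window that tolerates indel- or intron-sliding-induced
shifts, labelled alphabetically (A..Z, AA, AB, ...), and laid out as a
gene x intron-position presence/phase matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .phylo import Msa
from .seqcore import GeneModel

logger = logging.getLogger(__name__)


class GeneStructError(ValueError):
    pass


@dataclass
class IntronRecord:
    """One intron of a gene model, located within the CDS.

    ``cds_offset`` is the number of coding nucleotides preceding the intron;
    phase = cds_offset mod 3.  ``codon_index`` (1-based) is the codon the
    intron interrupts (phases 1, 2) or the codon immediately following it
    (phase 0)."""

    gene_id: str
    cds_offset: int
    phase: int
    codon_index: int
    donor: str | None = None
    acceptor: str | None = None

    def __post_init__(self) -> None:
        if self.cds_offset < 1:
            raise GeneStructError(
                f"{self.gene_id}: intron at cds_offset {self.cds_offset} < 1"
            )
        if self.phase != self.cds_offset % 3:
            raise GeneStructError(
                f"{self.gene_id}: phase {self.phase} != offset mod 3"
            )
        expect = (
            self.cds_offset // 3 + 1
            if self.phase == 0
            else (self.cds_offset - 1) // 3 + 1
        )
        if self.codon_index != expect:
            raise GeneStructError(
                f"{self.gene_id}: codon_index {self.codon_index} != {expect}"
            )


@dataclass
class MappedIntron:
    """An intron placed on the alignment: 1-based column plus phase."""

    gene_id: str
    column: int
    phase: int
    codon_index: int = 0


@dataclass
class IntronColumn:
    """A cluster of homologous intron positions.

    ``label`` runs A..Z then AA, AB, ... in order of the anchor column (the
    smallest member column); ``consensus_phase`` is the modal member phase.
    """

    label: str
    anchor: int
    members: list[MappedIntron]
    consensus_phase: int
    phase_exceptions: list[str] = field(default_factory=list)


def introns_from_gene_model(gene: GeneModel) -> list[IntronRecord]:
    """Derive intron records from consecutive exon pairs of a gene model.

    Only introns between the translation start and stop enter (the exon
    table is assumed to span exactly the CDS); ``cds_offset`` is the
    cumulative exon length before each inter-exon gap.  Donor/acceptor
    dinucleotides are read off the genomic sequence when present.
    """
    introns: list[IntronRecord] = []
    cum = 0
    for k, (start, end) in enumerate(gene.exons[:-1]):
        cum += end - start
        nxt_start = gene.exons[k + 1][0]
        donor = acceptor = None
        if gene.genomic is not None:
            seq = gene.genomic[end:nxt_start].upper()
            donor, acceptor = seq[:2], seq[-2:]
        phase = cum % 3
        codon_index = cum // 3 + 1 if phase == 0 else (cum - 1) // 3 + 1
        introns.append(
            IntronRecord(gene.id, cum, phase, codon_index, donor, acceptor)
        )
    return introns


def map_intron_to_alignment(
    intron: IntronRecord,
    msa: Msa,
    row_id: str,
    sp_len: int = 0,
) -> MappedIntron:
    """Project an intron onto the protein alignment.

    ``sp_len`` shifts codon indices when the alignment holds mature
    sequences but the gene model covers the full CDS.  Introns falling
    inside the signal peptide cannot be placed on a mature-only alignment
    and raise an error (flag upstream and map them on the full alignment).
    """
    residue_index = intron.codon_index - sp_len
    if residue_index < 1:
        raise GeneStructError(
            f"{intron.gene_id}: intron in codon {intron.codon_index} lies "
            f"inside the signal peptide (sp_len={sp_len})"
        )
    cols = msa.ungapped_to_column(row_id)
    if residue_index > len(cols):
        raise GeneStructError(
            f"{intron.gene_id}: codon {intron.codon_index} beyond row "
            f"{row_id!r} length {len(cols)}"
        )
    return MappedIntron(
        intron.gene_id, cols[residue_index - 1], intron.phase,
        intron.codon_index,
    )


def column_label(index: int) -> str:
    """Spreadsheet-style labels: 0 -> A, 25 -> Z, 26 -> AA, 35 -> AJ."""
    out = ""
    index += 1
    while index > 0:
        index, rem = divmod(index - 1, 26)
        out = chr(ord("A") + rem) + out
    return out


def cluster_homologous_introns(
    mapped: Iterable[MappedIntron], window: int = 2
) -> list[IntronColumn]:
    """Single-linkage clustering of mapped introns along the column axis.

    Introns whose columns are within ``window`` of a cluster member join the
    cluster (phase-agnostic: intron sliding can change phase).  Clusters are
    labelled alphabetically by anchor column (the smallest member column).
    A cluster chaining across more than 6 columns triggers a warning, since
    positional homology becomes doubtful at that span.
    """
    mapped = sorted(mapped, key=lambda m: (m.column, m.gene_id, m.phase))
    clusters: list[list[MappedIntron]] = []
    for m in mapped:
        if clusters and m.column - clusters[-1][-1].column <= window:
            clusters[-1].append(m)
        else:
            clusters.append([m])
    out: list[IntronColumn] = []
    for k, members in enumerate(clusters):
        anchor = min(m.column for m in members)
        span = max(m.column for m in members) - anchor
        label = column_label(k)
        if span > 6:
            warnings.warn(
                f"intron cluster {label} chains across {span + 1} columns; "
                "positional homology is doubtful"
            )
        phases = [m.phase for m in members]
        consensus = int(np.bincount(phases, minlength=3).argmax())
        exceptions = [m.gene_id for m in members if m.phase != consensus]
        out.append(IntronColumn(label, anchor, members, consensus, exceptions))
    return out


def intron_matrix(
    clusters: Sequence[IntronColumn],
    genes: Sequence[str],
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Gene x intron-position matrix; cells carry the phase (0/1/2) or NaN.

    Rows are ordered by group then id so homologous structures sit together;
    genes absent from every cluster still appear (all-empty rows), genes in
    clusters but not listed are logged and omitted.
    """
    groups = groups or {}
    listed = set(genes)
    for cl in clusters:
        for m in cl.members:
            if m.gene_id not in listed:
                logger.info("gene %s has mapped introns but no gene-model row",
                            m.gene_id)
    order = sorted(genes, key=lambda g: (groups.get(g, "~"), g))
    df = pd.DataFrame(
        np.nan, index=order, columns=[c.label for c in clusters], dtype=float
    )
    for cl in clusters:
        for m in cl.members:
            if m.gene_id in listed:
                df.loc[m.gene_id, cl.label] = m.phase
    return df


def shared_intron_report(
    matrix: pd.DataFrame, groups: Mapping[str, str]
) -> dict[str, dict]:
    """Which groups carry each intron position; private/universal flags.

    A label carried by exactly one gene is "private"; one present in every
    group represented in the matrix is "universal".
    """
    present_groups = sorted({groups.get(g, "?") for g in matrix.index})
    report: dict[str, dict] = {}
    for label in matrix.columns:
        carriers = [g for g in matrix.index if not np.isnan(matrix.loc[g, label])]
        carrier_groups = sorted({groups.get(g, "?") for g in carriers})
        report[label] = {
            "carriers": carriers,
            "groups": carrier_groups,
            "private": len(carriers) == 1,
            "universal": carrier_groups == present_groups and bool(carriers),
        }
    return report


def validate_splice_sites(
    gene: GeneModel, genomic: str | None = None
) -> list[dict]:
    """Check each intron for the canonical GT...AG donor/acceptor pair."""
    genomic = genomic if genomic is not None else gene.genomic
    if genomic is None:
        raise GeneStructError(f"gene {gene.id!r}: no genomic sequence")
    out = []
    for k in range(len(gene.exons) - 1):
        i_start = gene.exons[k][1]
        i_end = gene.exons[k + 1][0]
        if i_end > len(genomic):
            raise GeneStructError(
                f"gene {gene.id!r}: intron {k} beyond genomic sequence"
            )
        seq = genomic[i_start:i_end].upper()
        donor, acceptor = seq[:2], seq[-2:]
        out.append({
            "index": k,
            "donor": donor,
            "acceptor": acceptor,
            "canonical": donor == "GT" and acceptor == "AG",
        })
    return out
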