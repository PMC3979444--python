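"""Domain types, file I/O, and curation filters for class-II peroxidase datasets.

The pipeline works on three kinds of records: protein sequences (possibly
carrying an N-terminal signal peptide), in-frame coding sequences, and gene
models given as ordered exon coordinate tables on a genomic sequence.  All
coordinates are 0-based, half-open, on the coding strand; GFF3 input (1-based,
closed) is converted on ingest.

Curation mirrors the standard preparation of a nonredundant peroxidase set:
within-species redundancy removal on the mature sequence, signal-peptide
stripping from an external annotation table, and a consistency check between
each protein and its coding sequence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}

LP_TYPES = ("MnP", "LiP", "VP", "CII", "CcP")


class SeqcoreError(ValueError):
    """Raised for malformed sequence input or violated preconditions."""


@dataclass
class ProteinRecord:
    """One peroxidase protein with species/order/type metadata.

    ``residues`` may include the signal peptide; ``sp_len`` records how many
    N-terminal residues belong to it (0 = none or unknown).
    """

    id: str
    residues: str
    species: str = ""
    order: str = ""
    sp_len: int = 0
    declared_type: str | None = None

    def __post_init__(self) -> None:
        bad = sorted(set(self.residues) - AA_ALPHABET)
        if bad:
            raise SeqcoreError(
                f"record {self.id!r}: invalid residue(s) {''.join(bad)!r} "
                "(allowed: 20 amino acids plus X)"
            )
        if not (0 <= self.sp_len < max(len(self.residues), 1)):
            raise SeqcoreError(
                f"record {self.id!r}: sp_len {self.sp_len} out of range for "
                f"length {len(self.residues)}"
            )
        if self.declared_type is not None and self.declared_type not in LP_TYPES:
            raise SeqcoreError(
                f"record {self.id!r}: unknown declared type {self.declared_type!r}"
            )

    @property
    def mature(self) -> str:
        """Residues with the annotated signal peptide removed."""
        return self.residues[self.sp_len :]

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneModel:
    """Ordered exon coordinates on the coding strand defining a CDS.

    Exons are (start, end) 0-based half-open, strictly increasing and
    non-overlapping.  ``genomic`` optionally carries the nucleotide string the
    coordinates index into (spanning at least the last exon end).
    """

    id: str
    exons: list[tuple[int, int]]
    genomic: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise SeqcoreError(f"gene model {self.id!r}: no exons")
        prev_end = -1
        for start, end in self.exons:
            if not (0 <= start < end):
                raise SeqcoreError(
                    f"gene model {self.id!r}: bad exon ({start}, {end})"
                )
            if start < prev_end:
                raise SeqcoreError(
                    f"gene model {self.id!r}: exons overlap or are unordered "
                    f"at ({start}, {end})"
                )
            prev_end = end
        if self.genomic is not None and self.exons[-1][1] > len(self.genomic):
            raise SeqcoreError(
                f"gene model {self.id!r}: exon end {self.exons[-1][1]} beyond "
                f"genomic length {len(self.genomic)}"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced_cds(self) -> str:
        if self.genomic is None:
            raise SeqcoreError(f"gene model {self.id!r}: no genomic sequence")
        return "".join(self.genomic[s:e] for s, e in self.exons)

    @property
    def complete(self) -> bool:
        """True when the exon total is a whole number of codons."""
        return self.cds_length % 3 == 0


@dataclass
class Dataset:
    """A curated bundle: proteins plus optional gene models and CDS per id."""

    proteins: list[ProteinRecord]
    genes: dict[str, GeneModel] = field(default_factory=dict)
    cds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.proteins]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SeqcoreError(f"duplicate protein ids: {', '.join(dupes)}")
        known = set(ids)
        for bag, label in ((self.genes, "gene model"), (self.cds, "CDS")):
            orphans = sorted(set(bag) - known)
            if orphans:
                raise SeqcoreError(
                    f"{label} ids without a protein record: {', '.join(orphans)}"
                )

    def protein(self, pid: str) -> ProteinRecord:
        for p in self.proteins:
            if p.id == pid:
                return p
        raise KeyError(pid)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, kind: str = "protein") -> list[ProteinRecord]:
    """Read a FASTA file into protein records.

    Headers of the form ``id|species|order|type`` populate the metadata
    fields; any other header is used whole as the id.  With
    ``kind="nucleotide"`` no residue validation is applied and metadata
    parsing still works (used for CDS files via :func:`read_cds_fasta`).
    """
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description or rec.id
        parts = header.split("|")
        declared = None
        species = order = ""
        if len(parts) >= 4:
            pid, species, order, declared = (p.strip() for p in parts[:4])
        elif len(parts) > 1:
            pid = parts[0].strip()
            species = parts[1].strip() if len(parts) > 1 else ""
            order = parts[2].strip() if len(parts) > 2 else ""
        else:
            pid = header.strip()
        if pid in seen:
            raise SeqcoreError(f"duplicate id in {path.name}: {pid!r}")
        seen.add(pid)
        seq = str(rec.seq).upper()
        if kind == "protein":
            records.append(
                ProteinRecord(
                    id=pid, residues=seq, species=species, order=order,
                    declared_type=declared or None,
                )
            )
        else:
            r = ProteinRecord.__new__(ProteinRecord)  # skip AA validation
            r.id, r.residues, r.species, r.order = pid, seq, species, order
            r.sp_len, r.declared_type = 0, None
            records.append(r)
    if not records:
        raise SeqcoreError(f"no records in {path}")
    return records


def read_cds_fasta(path: str | Path) -> dict[str, str]:
    """Read in-frame coding sequences as an id -> nucleotide-string map."""
    return {r.id: r.residues for r in read_fasta(path, kind="nucleotide")}


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records with ``id|species|order|type`` headers (byte round-trip)."""
    with open(path, "w") as fh:
        for rec in records:
            if rec.species or rec.order or rec.declared_type:
                header = "|".join(
                    [rec.id, rec.species, rec.order, rec.declared_type or ""]
                )
            else:
                header = rec.id
            fh.write(f">{header}\n{rec.residues}\n")


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

def read_signal_peptides(path: str | Path) -> dict[str, int]:
    """Read a TSV of (id, cleavage position) signal-peptide annotations.

    The cleavage position is the number of residues in the signal peptide,
    i.e. the 0-based index of the first mature residue.  A header line is
    tolerated.
    """
    table: dict[str, int] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            try:
                table[row[0]] = int(row[1])
            except (IndexError, ValueError):
                if row[0].lower() in {"id", "name"}:
                    continue
                raise SeqcoreError(f"bad signal-peptide row: {row!r}")
    return table


def read_exclusions(path: str | Path) -> set[str]:
    """Read a one-column (or first-column) TSV of record ids to discard.

    Used for incompletely processed transcripts and similar curator flags
    that cannot be detected automatically.
    """
    out: set[str] = set()
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if row and not row[0].startswith("#") and row[0].lower() != "id":
                out.add(row[0])
    return out


def read_gene_models_tsv(path: str | Path) -> dict[str, GeneModel]:
    """Read exon tables from a 4-column TSV: id, exon_index, start, end.

    Coordinates are 0-based half-open on the coding strand.
    """
    exons: dict[str, list[tuple[int, tuple[int, int]]]] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0].lower() == "id":
                continue
            pid, idx, start, end = row[0], int(row[1]), int(row[2]), int(row[3])
            exons.setdefault(pid, []).append((idx, (start, end)))
    return {
        pid: GeneModel(id=pid, exons=[e for _, e in sorted(lst)])
        for pid, lst in exons.items()
    }


def read_gene_models_gff3(path: str | Path) -> dict[str, GeneModel]:
    """Read CDS features from a GFF3 file, converting 1-based closed to
    0-based half-open coordinates.  The feature's ID / Parent attribute
    groups exons into one model; only '+'-strand models are supported."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        if feat.strand == "-":
            raise SeqcoreError(
                "minus-strand gene models are not supported; provide "
                "coding-strand coordinates"
            )
        pid = feat.attributes.get("Parent", feat.attributes.get("ID", [feat.id]))[0]
        exons.setdefault(pid, []).append((feat.start - 1, feat.end))
    return {
        pid: GeneModel(id=pid, exons=sorted(lst)) for pid, lst in exons.items()
    }


# ---------------------------------------------------------------------------
# Curation operations
# ---------------------------------------------------------------------------

def strip_signal_peptide(rec: ProteinRecord, cleavage: int) -> ProteinRecord:
    """Return a mature record with the first ``cleavage`` residues removed.

    The original record's ``sp_len`` is set to ``cleavage`` so the annotation
    survives on the full-length copy; the returned record is mature
    (``sp_len == 0``).  ``cleavage == 0`` returns an unchanged copy.
    """
    if not (0 <= cleavage < len(rec.residues)):
        raise SeqcoreError(
            f"record {rec.id!r}: cleavage {cleavage} not in [0, "
            f"{len(rec.residues)})"
        )
    rec.sp_len = cleavage
    return replace(rec, residues=rec.residues[cleavage:], sp_len=0)


def dedupe_within_species(
    records: Iterable[ProteinRecord],
) -> tuple[list[ProteinRecord], list[tuple[ProteinRecord, str]]]:
    """Keep one copy per (species, mature sequence); drop the rest.

    Several strains of one fungal species often deposit the same enzyme;
    among identical mature sequences from one species the record with the
    lexicographically smallest id is kept, making the operation idempotent
    and order-independent.  Identical sequences from *different* species are
    all kept.  Returns (kept, dropped-with-reason), both in input order.
    """
    records = list(records)
    best: dict[tuple[str, str], str] = {}
    for rec in records:
        key = (rec.species, rec.mature)
        if key not in best or rec.id < best[key]:
            best[key] = rec.id
    kept, dropped = [], []
    for rec in records:
        winner = best[(rec.species, rec.mature)]
        if rec.id == winner:
            kept.append(rec)
        else:
            dropped.append(
                (rec, f"duplicate of {winner} within species {rec.species!r}")
            )
    return kept, dropped


@dataclass
class CdsReport:
    """Outcome of a protein/CDS consistency check."""

    id: str
    consistent: bool
    mode: str | None  # "full" or "mature" when consistent
    mismatches: list[int]  # 0-based residue positions, best candidate mode


def translate_cds(cds: str, id_: str = "?") -> str:
    """Standard-code translation, rejecting internal stops and trimming a
    trailing stop codon."""
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3:
        raise SeqcoreError(f"CDS {id_!r}: length {len(cds)} not divisible by 3")
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise SeqcoreError(
            f"CDS {id_!r}: internal stop codon at codon {prot.index('*') + 1}"
        )
    return prot


def check_cds_consistency(protein: ProteinRecord, cds: str) -> CdsReport:
    """Check that the CDS translates to the protein, full-length or mature.

    Both interpretations are tried: the translation may include the signal
    peptide ("full") or start at the mature N-terminus ("mature").  When
    neither matches, the mismatch positions against the closer candidate are
    reported.
    """
    trans = translate_cds(cds, protein.id)
    candidates = {"full": protein.residues}
    if protein.sp_len:
        candidates["mature"] = protein.mature
    results = {}
    for mode, target in candidates.items():
        if len(trans) != len(target):
            results[mode] = None
            continue
        results[mode] = [i for i, (a, b) in enumerate(zip(trans, target)) if a != b]
    for mode in ("full", "mature"):
        if results.get(mode) == []:
            return CdsReport(protein.id, True, mode, [])
    best_mode = min(
        (m for m, r in results.items() if r is not None),
        key=lambda m: len(results[m]),
        default=None,
    )
    return CdsReport(
        protein.id, False, None,
        results[best_mode] if best_mode else [],
    )
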