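"""Readers and writers for the formats the pipeline touches, plus the
gene-structure summarizer.

Internal coordinates are 0-based half-open throughout the package; every
rendered table is 1-based inclusive (stated in the file header line).
"""

from __future__ import annotations

import os
import tempfile
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues accepted in a ProteinRecord; X is allowed but never matches a motif
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ProteinRecord:
    """A protein sequence with its species of origin.

    The FASTA description may carry genus and species epithet as the second
    and third whitespace-separated tokens; both default to empty strings.
    """

    id: str
    sequence: str
    genus: str = ""
    species_epithet: str = ""
    source_note: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("protein record with empty id")
        if not self.sequence:
            raise FormatError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise FormatError(
                f"{self.id}: illegal residue(s) {sorted(bad)!r} "
                "(expected the 20 amino acids or X; gaps are not allowed)"
            )

    @property
    def species(self) -> str:
        return f"{self.genus} {self.species_epithet}".strip()


@dataclass
class GeneStructureSummary:
    gene_id: str
    n_introns: int
    cds_length_nt: int


def read_fasta(path: str | os.PathLike) -> list[ProteinRecord]:
    """Read a protein FASTA into a list of :class:`ProteinRecord`.

    Sequences are uppercased. Duplicate ids and illegal residues are
    rejected. Genus and species epithet are taken from the description
    line when present (``>id Genus epithet ...``).
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        tokens = rec.description.split()
        genus = tokens[1] if len(tokens) > 2 else ""
        epithet = tokens[2] if len(tokens) > 2 else ""
        note = " ".join(tokens[3:]) if len(tokens) > 3 else ""
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                genus=genus,
                species_epithet=epithet,
                source_note=note,
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.genus} {rec.species_epithet}" if rec.genus else ""
            note = f" {rec.source_note}" if rec.source_note else ""
            fh.write(f">{rec.id}{desc}{note}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# gene structure

def summarize_gene_structure(
    gff3_path: str | os.PathLike,
) -> tuple[list[GeneStructureSummary], Counter]:
    """Summarize intron counts per gene from a GFF3 file.

    Splice variants are collapsed to a single primary transcript per gene:
    the mRNA with the largest total exon length, ties broken by transcript
    id. ``n_introns`` is the primary transcript's exon count minus one.
    Returns the per-gene summaries and an intron-count histogram whose
    counts sum to the number of genes.
    """
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    summaries: list[GeneStructureSummary] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if not mrnas:
            continue
        best = None
        for mrna in mrnas:
            exons = list(db.children(mrna, featuretype="exon", order_by="start"))
            for ex in exons:
                if ex.start < mrna.start or ex.end > mrna.end:
                    raise FormatError(
                        f"exon {ex.id or ex.start} outside bounds of mRNA {mrna.id}"
                    )
            total = sum(ex.end - ex.start + 1 for ex in exons)
            key = (-total, mrna.id)
            if best is None or key < best[0]:
                best = (key, mrna, exons)
        _, mrna, exons = best
        cds = list(db.children(mrna, featuretype="CDS", order_by="start"))
        cds_len = sum(c.end - c.start + 1 for c in cds) if cds else sum(
            ex.end - ex.start + 1 for ex in exons
        )
        summaries.append(
            GeneStructureSummary(
                gene_id=gene.id,
                n_introns=max(len(exons) - 1, 0),
                cds_length_nt=cds_len,
            )
        )
    histogram = Counter(s.n_introns for s in summaries)
    return summaries, histogram


# ---------------------------------------------------------------------------
# domain tables

DOMAIN_TABLE_COLUMNS = [
    "protein_id",
    "start",
    "end",
    "tetramer",
    "tail",
    "variant_class",
    "zf_type",
    "spacer_pattern",
    "terminal",
]

_TABLE_HEADER_NOTE = "# coordinates are 1-based inclusive"


def write_domain_table(hits: Sequence, path: str | os.PathLike) -> None:
    """Write WRKY domain calls as TSV with 1-based inclusive coordinates.

    Round-trips through :func:`read_domain_table`.
    """
    with open(path, "w") as fh:
        fh.write(_TABLE_HEADER_NOTE + "\n")
        fh.write("\t".join(DOMAIN_TABLE_COLUMNS) + "\n")
        for h in hits:
            zf = h.zinc_finger
            fh.write(
                "\t".join(
                    [
                        h.protein_id,
                        str(h.start + 1),
                        str(h.end),
                        h.heptapeptide.tetramer,
                        h.heptapeptide.tail,
                        h.heptapeptide.variant_class.name,
                        zf.zf_type.name if zf is not None else ".",
                        zf.spacer_pattern if zf is not None else ".",
                        h.terminal.name,
                    ]
                )
                + "\n"
            )


def read_domain_table(path: str | os.PathLike) -> list:
    """Read a domain-call TSV written by :func:`write_domain_table`."""
    from .motif_scan import (
        HeptapeptideHit,
        Terminal,
        VariantClass,
        WRKYDomainHit,
        ZincFingerType,
        ZincFingerHit,
        parse_zf_pattern,
    )

    hits = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    if not lines:
        return hits
    header = lines[0].split("\t")
    if header != DOMAIN_TABLE_COLUMNS:
        raise FormatError(f"unexpected domain-table header in {path}")
    for ln in lines[1:]:
        if not ln:
            continue
        (pid, start, end, tetramer, tail, vclass, zf_type, spacer, terminal) = ln.split("\t")
        start0 = int(start) - 1
        end0 = int(end)
        if zf_type == ".":
            zf = None
        else:
            a, b, c, last = parse_zf_pattern(spacer)
            # reconstruct coordinating-residue positions relative to the
            # domain end, which the writer anchors at the last zf residue
            p4 = end0 - 1
            p3 = p4 - (c + 1)
            p2 = p3 - (b + 1)
            p1 = p2 - (a + 1)
            zf = ZincFingerHit(
                positions=(p1, p2, p3, p4),
                zf_type=ZincFingerType[zf_type],
                spacer_pattern=spacer,
            )
        hepta_start = start0 + 10 if start0 >= 0 else 0
        # the writer does not store the heptapeptide offset; it is 10 from
        # the domain start except when truncated at the sequence boundary
        hits.append(
            WRKYDomainHit(
                protein_id=pid,
                start=start0,
                end=end0,
                heptapeptide=HeptapeptideHit(
                    start=hepta_start,
                    tetramer=tetramer,
                    tail=tail,
                    variant_class=VariantClass[vclass],
                ),
                zinc_finger=zf,
                terminal=Terminal[terminal],
            )
        )
    return hits
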