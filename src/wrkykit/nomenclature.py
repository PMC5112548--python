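"""Orthology-based gene nomenclature.

Names follow the convention GenusSpecies-prefix + "WRKY" + reference
ortholog number, with hyphenated paralog indices when several genes of
one species map to the same reference number (e.g. OsWRKY46-1 and
OsWRKY46-2). The species prefix defaults to the genus initial (upper
case) plus the epithet initial (lower case); on collision with an
already-taken prefix the epithet contribution is extended to its first
syllable and then letter by letter, using two to four epithet letters.

Reference assignment scores the query's C-terminal WRKY domain sequence
against each reference domain by global alignment (BLOSUM62, affine
gaps) and keeps the best-scoring reference; rice references serve
monocot queries and Arabidopsis references serve dicots and all other
lineages.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices


class Lineage(Enum):
    MONOCOT_REF = "monocot"
    DICOT_REF = "dicot"


@dataclass(frozen=True)
class ReferenceEntry:
    reference_name: str  # e.g. "AtWRKY33"
    lineage: Lineage
    domain_sequence: str

    @property
    def wrky_number(self) -> int:
        m = re.search(r"WRKY(\d+)", self.reference_name)
        if m is None:
            raise ValueError(f"no WRKY number in {self.reference_name!r}")
        return int(m.group(1))


@dataclass(frozen=True)
class NameAssignment:
    query_id: str
    prefix: str
    wrky_number: int
    score: float
    paralog_index: Optional[int] = None
    final_name: str = ""


class PrefixCollisionError(ValueError):
    """Raised when no unique prefix exists within four epithet letters."""


_VOWELS = set("aeiou")


def _first_syllable(epithet: str) -> str:
    """First syllable of the epithet: everything up to, but excluding, the
    consonant that opens the second syllable (at least two letters)."""
    s = epithet.lower()
    i = 0
    while i < len(s) and s[i] not in _VOWELS:
        i += 1
    while i < len(s) and s[i] in _VOWELS:
        i += 1
    vowel_end = i
    while i < len(s) and s[i] not in _VOWELS:
        i += 1
    end = i - 1 if i > vowel_end and i < len(s) else i
    end = max(end, 2)
    return s[: min(end, 4)]


def species_prefix(genus: str, species_epithet: str, taken_prefixes: set[str]) -> str:
    """Build a unique species prefix and register it in ``taken_prefixes``.

    Default is genus initial + epithet initial (e.g. "At"). On collision
    the epithet part grows to the epithet's first syllable, then letter by
    letter up to four epithet letters.
    """
    if not genus.isalpha() or not species_epithet.isalpha():
        raise ValueError("genus and species epithet must be non-empty alphabetic")
    g = genus[0].upper()
    candidates = [g + species_epithet[0].lower()]
    syllable = _first_syllable(species_epithet)
    for n in range(len(syllable), 5):
        candidates.append(g + species_epithet[:n].lower())
    seen: set[str] = set()
    for cand in candidates:
        if cand in seen:
            continue
        seen.add(cand)
        if cand not in taken_prefixes:
            taken_prefixes.add(cand)
            return cand
    raise PrefixCollisionError(
        f"no unique prefix for {genus} {species_epithet} within 4 epithet letters"
    )


# ---------------------------------------------------------------------------
# reference panel

def load_references(path) -> list[ReferenceEntry]:
    """Read a reference table TSV with columns name, lineage, domain_sequence."""
    entries = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#") and ln.strip()]
    if not lines or lines[0].split("\t") != ["name", "lineage", "domain_sequence"]:
        raise ValueError(f"unexpected reference-table header in {path}")
    for ln in lines[1:]:
        name, lineage, seq = ln.split("\t")
        entries.append(
            ReferenceEntry(
                reference_name=name,
                lineage=Lineage(lineage),
                domain_sequence=seq,
            )
        )
    return entries


def packaged_references() -> list[ReferenceEntry]:
    """The bundled synthetic reference panel (generated domain sequences
    standing in for the Arabidopsis/rice reference sets, which are not
    redistributable here)."""
    with resources.as_file(
        resources.files("wrkykit.data") / "synthetic_reference_domains.tsv"
    ) as p:
        return load_references(p)


# ---------------------------------------------------------------------------
# orthology assignment

def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def _identity(aln) -> float:
    a, b = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(a, b))
    return matches / max(len(a), 1)


def assign_orthology(
    query_domain: str,
    references: Sequence[ReferenceEntry],
    lineage: Lineage,
) -> tuple[ReferenceEntry, float]:
    """Best reference for a query domain sequence under global alignment.

    Only references of the requested lineage are considered. Ties on the
    alignment score are broken by higher full-length identity, then by
    lower reference number, making the result invariant to the input
    order of the references.
    """
    pool = [r for r in references if r.lineage is lineage]
    if not pool:
        raise ValueError(f"no references for lineage {lineage}")
    aligner = _aligner()
    best: tuple[float, float, int, ReferenceEntry] | None = None
    for ref in pool:
        alns = aligner.align(query_domain, ref.domain_sequence)
        score = alns.score
        ident = _identity(alns[0])
        key = (score, ident, -ref.wrky_number)
        if best is None or key > best[:3]:
            best = (*key, ref)
    return best[3], best[0]


def number_paralogs(
    assignments: Sequence[NameAssignment],
    coordinates: Optional[Mapping[str, float]] = None,
) -> list[NameAssignment]:
    """Finalize names, adding hyphenated paralog indices where needed.

    Queries sharing (prefix, wrky_number) of group size one keep the bare
    name; larger groups get "-1", "-2", ... ordered by genomic coordinate
    when supplied, else lexicographically by query id. Idempotent.
    """
    prefixes = {a.prefix for a in assignments}
    if len(prefixes) > 1:
        raise ValueError("paralog numbering expects assignments of a single species")
    groups: dict[tuple[str, int], list[NameAssignment]] = {}
    for a in assignments:
        groups.setdefault((a.prefix, a.wrky_number), []).append(a)

    def order_key(a: NameAssignment):
        if coordinates is not None and a.query_id in coordinates:
            return (0, coordinates[a.query_id], a.query_id)
        return (1, 0.0, a.query_id)

    out = []
    for (prefix, number), members in groups.items():
        members = sorted(members, key=order_key)
        if len(members) == 1:
            a = members[0]
            out.append(
                replace(a, paralog_index=None, final_name=f"{prefix}WRKY{number}")
            )
        else:
            for idx, a in enumerate(members, start=1):
                out.append(
                    replace(
                        a,
                        paralog_index=idx,
                        final_name=f"{prefix}WRKY{number}-{idx}",
                    )
                )
    out.sort(key=lambda a: a.query_id)
    return out


def name_species(
    query_domains: Mapping[str, str],
    references: Sequence[ReferenceEntry],
    lineage: Lineage,
    prefix: str,
    coordinates: Optional[Mapping[str, float]] = None,
) -> list[NameAssignment]:
    """Assign final names to all queries of one species."""
    assignments = []
    for qid in sorted(query_domains):
        ref, score = assign_orthology(query_domains[qid], references, lineage)
        assignments.append(
            NameAssignment(
                query_id=qid,
                prefix=prefix,
                wrky_number=ref.wrky_number,
                score=score,
            )
        )
    return number_paralogs(assignments, coordinates=coordinates)


def write_name_table(assignments: Iterable[NameAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tfinal_name\tprefix\twrky_number\tparalog_index\tscore\n")
        for a in assignments:
            idx = "" if a.paralog_index is None else str(a.paralog_index)
            fh.write(
                f"{a.query_id}\t{a.final_name}\t{a.prefix}\t{a.wrky_number}\t{idx}\t{a.score:g}\n"
            )
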