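"""Synthetic proteomes, families, alignments and triplets with planted truth.

The generator emulates the statistical structure the annotation and
phylogeny stages assume: ~60-aa WRKY domains with the canonical
heptapeptide in its N- or C-terminal context (D-G-Y-N-W-R-K-Y-G-Q-K
versus D-G-Y-R-W-R-K-Y-G-Q-K) followed by a C2H2 zinc finger; variant
tetramers injected from the accepted catalog; chimeric architectures
with accessory-domain intervals; orthologous families with paralogs
across species; clade-structured labelled families for grouping tests;
and sequence triplets under an equal-rate Poisson substitution process.

Background residues are drawn uniformly over the 20 amino acids by
default (configurable); after assembly any background window that
happens to spell a catalogued heptapeptide signature is re-drawn, so a
zero-mutation proteome contains exactly the planted domain set. The
internal spacer positions of planted zinc fingers avoid C and H so the
planted coordinating residues are the ones a scanner finds.

Every operation takes an explicit seed and is byte-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .architecture import AccessoryDomain, AccessoryDomainHit, ArchitectureClass
from .core_io import AMINO_ACIDS, ProteinRecord
from .motif_scan import (
    CANONICAL_TAIL,
    CANONICAL_TETRAMER,
    Terminal,
    VARIANT_TETRAMERS,
    VariantClass,
    scan_heptapeptide,
)
from .nomenclature import Lineage, ReferenceEntry
from .phylo import AlignedBlock

#: residues safe for zinc-finger spacer positions (no C or H, which could
#: shift the coordinating-residue positions a scanner reports)
_ZF_SAFE = "".join(ch for ch in AMINO_ACIDS if ch not in "CH")


class SpecError(ValueError):
    """Raised for an internally inconsistent generator specification."""


@dataclass
class FamilySpec:
    """Study conditions for a synthetic proteome.

    Defaults give a 500-protein proteome (10 species x 50 families x 1
    paralog) with a quarter double-domain proteins, a small chimeric
    fraction, occasional variant tetramers, and no within-domain
    mutation.
    """

    n_species: int = 10
    families_per_species: int = 50
    paralog_range: tuple[int, int] = (1, 1)
    double_domain_fraction: float = 0.25
    chimera_fraction: float = 0.05
    chimera_classes: tuple[ArchitectureClass, ...] = (
        ArchitectureClass.KINASE_WRKY,
        ArchitectureClass.DOUBLE_WRKY_KINASE,
        ArchitectureClass.TIR_WRKY,
        ArchitectureClass.TIR_LRR_WRKY,
        ArchitectureClass.B3_WRKY,
        ArchitectureClass.WRKY_ZF_SBP,
        ArchitectureClass.TRIPLE_WRKY_ZF_SBP,
        ArchitectureClass.WRKY_CBS3,
    )
    variant_injection: float = 0.10
    variant_pool: tuple[str, ...] = tuple(sorted(VARIANT_TETRAMERS))
    mutation_rate: float = 0.0
    background_length: tuple[int, int] = (25, 60)
    background_composition: Optional[dict[str, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.double_domain_fraction,
            self.chimera_fraction,
            self.variant_injection,
            self.mutation_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise SpecError(f"probability {p} outside [0, 1]")
        if self.paralog_range[0] < 1 or self.paralog_range[0] > self.paralog_range[1]:
            raise SpecError(f"bad paralog range {self.paralog_range}")
        bad = set(self.variant_pool) - VARIANT_TETRAMERS
        if bad:
            raise SpecError(f"variant pool outside the accepted catalog: {sorted(bad)}")


@dataclass(frozen=True)
class PlantedDomain:
    start: int  # 0-based half-open interval, as a scanner reports it
    end: int
    hepta_start: int
    tetramer: str
    tail: str
    variant_class: VariantClass
    terminal: Terminal


@dataclass
class ProteinTruth:
    protein_id: str
    species: str
    family_number: int
    domains: list[PlantedDomain]
    architecture: ArchitectureClass


@dataclass
class SyntheticTruth:
    spec: FamilySpec
    proteins: dict[str, ProteinTruth] = field(default_factory=dict)

    @property
    def planted_domains(self) -> dict[str, list[PlantedDomain]]:
        return {pid: t.domains for pid, t in self.proteins.items()}


# concrete domain layouts per architecture class, as ordered tokens;
# "WRKY" tokens become planted domains, everything else an accessory span
_CHIMERA_LAYOUT: dict[ArchitectureClass, tuple[str, ...]] = {
    ArchitectureClass.TRIPLE_WRKY_ZF_SBP: ("WRKY", "WRKY", "WRKY", "ZF_SBP"),
    ArchitectureClass.WRKY_CBS3: ("WRKY", "CBS", "CBS", "CBS"),
    ArchitectureClass.KINASE_WRKY: ("KINASE", "WRKY"),
    ArchitectureClass.KINASE_DOUBLE_WRKY: ("KINASE", "WRKY", "WRKY"),
    ArchitectureClass.DOUBLE_WRKY_KINASE: ("WRKY", "WRKY", "KINASE"),
    ArchitectureClass.PAH_DOUBLE_WRKY_KINASE: ("PAH", "WRKY", "WRKY", "KINASE"),
    ArchitectureClass.PROTEASE_WRKY: ("ULP_PROTEASE", "WRKY"),
    ArchitectureClass.TIR_WRKY: ("TIR", "WRKY"),
    ArchitectureClass.TIR_DOUBLE_WRKY: ("TIR", "WRKY", "WRKY"),
    ArchitectureClass.TIR_LRR_WRKY: ("TIR",) + ("LRR",) * 7 + ("WRKY",),
    ArchitectureClass.LRR_NAC_DOUBLE_WRKY: ("LRR", "LRR", "NAC", "WRKY", "WRKY"),
    ArchitectureClass.ATP_GRASP_WRKY: ("ATP_GRASP", "WRKY"),
    ArchitectureClass.B3_WRKY: ("B3", "WRKY"),
    ArchitectureClass.WRKY_ZF_SBP: ("WRKY", "ZF_SBP"),
}

_ACCESSORY_SPAN = {  # plausible domain lengths, residues
    "KINASE": 250,
    "TIR": 150,
    "LRR": 24,
    "NAC": 150,
    "B3": 110,
    "CBS": 55,
    "ZF_SBP": 75,
    "PAH": 65,
    "ULP_PROTEASE": 180,
    "ATP_GRASP": 190,
}


def _draw_residues(rng: np.random.Generator, n: int, alphabet: str = AMINO_ACIDS,
                   weights: Optional[Sequence[float]] = None) -> str:
    idx = rng.choice(len(alphabet), size=n, p=weights)
    return "".join(alphabet[i] for i in idx)


def _domain_segment(
    rng: np.random.Generator, tetramer: str, n_context: bool
) -> tuple[str, int, int]:
    """One planted WRKY domain segment.

    Returns (segment, heptapeptide offset, zinc-finger end offset). The
    segment starts 10 residues before the heptapeptide (covering the
    D-G-Y-N/R context) and ends at the last zinc-finger residue, so the
    segment boundaries are exactly the interval a scanner reports.
    """
    upstream = _draw_residues(rng, 6, _ZF_SAFE) + ("DGYN" if n_context else "DGYR")
    hepta = tetramer + CANONICAL_TAIL
    linker = _draw_residues(rng, 3, _ZF_SAFE)
    zf = (
        "C"
        + _draw_residues(rng, 4, _ZF_SAFE)
        + "C"
        + _draw_residues(rng, 23, _ZF_SAFE)
        + "H"
        + _draw_residues(rng, 1, _ZF_SAFE)
        + "H"
    )
    segment = upstream + hepta + linker + zf
    return segment, len(upstream), len(segment)


def _sanitize_background(
    seq: list[str], planted_hepta_starts: set[int], rng: np.random.Generator
) -> None:
    """Redraw residues creating unplanted heptapeptide signatures in place."""
    for _ in range(100):
        text = "".join(seq)
        spurious = [
            h.start
            for h in scan_heptapeptide(text)
            if h.start not in planted_hepta_starts
        ]
        if not spurious:
            return
        for pos in spurious:
            seq[pos] = _ZF_SAFE[rng.integers(len(_ZF_SAFE))]
    raise RuntimeError("could not sanitize background after 100 rounds")


def generate_proteome(
    spec: FamilySpec,
) -> tuple[list[ProteinRecord], list[AccessoryDomainHit], SyntheticTruth]:
    """Generate a proteome with planted domains, variants and chimeras.

    Deterministic given ``spec.seed``. Species are synthetic binomials
    with distinct genus initials ("Agenus synthetica", "Bgenus
    synthetica", ...); each family number appears once per species times
    the sampled paralog count.
    """
    rng = np.random.default_rng(spec.seed)
    weights = None
    alphabet = AMINO_ACIDS
    if spec.background_composition is not None:
        alphabet = "".join(sorted(spec.background_composition))
        total = sum(spec.background_composition.values())
        weights = [spec.background_composition[ch] / total for ch in alphabet]

    records: list[ProteinRecord] = []
    accessories: list[AccessoryDomainHit] = []
    truth = SyntheticTruth(spec=spec)

    if spec.n_species > 26:
        raise SpecError("at most 26 synthetic species supported")
    for s in range(1, spec.n_species + 1):
        genus = chr(ord("A") + s - 1) + "genus"
        epithet = "synthetica"
        species = f"{genus} {epithet}"
        for fam in range(1, spec.families_per_species + 1):
            n_paralogs = int(rng.integers(spec.paralog_range[0], spec.paralog_range[1] + 1))
            for par in range(1, n_paralogs + 1):
                pid = f"G{s}_F{fam}_P{par}"
                u = rng.random()
                if u < spec.chimera_fraction:
                    arch = spec.chimera_classes[rng.integers(len(spec.chimera_classes))]
                    tokens = _CHIMERA_LAYOUT[arch]
                elif u < spec.chimera_fraction + spec.double_domain_fraction:
                    arch = ArchitectureClass.DOUBLE_NC
                    tokens = ("WRKY", "WRKY")
                else:
                    arch = ArchitectureClass.SINGLE_C
                    tokens = ("WRKY",)
                n_wrky = tokens.count("WRKY")

                chunks: list[str] = []
                planted: list[tuple[int, int, int, str, bool]] = []  # start,end,hepta,tet,n_ctx
                acc_spans: list[tuple[str, int, int]] = []
                pos = 0
                wrky_seen = 0

                def bg(min_extra: int = 0) -> str:
                    lo, hi = spec.background_length
                    return _draw_residues(
                        rng, int(rng.integers(lo, hi + 1)) + min_extra, alphabet, weights
                    )

                lead = bg()
                chunks.append(lead)
                pos += len(lead)
                for tok in tokens:
                    if tok == "WRKY":
                        wrky_seen += 1
                        if rng.random() < spec.variant_injection:
                            tet = spec.variant_pool[rng.integers(len(spec.variant_pool))]
                        else:
                            tet = CANONICAL_TETRAMER
                        if n_wrky == 1:
                            n_ctx = False
                        else:
                            n_ctx = wrky_seen < n_wrky  # last domain gets C context
                        seg, hepta_off, _ = _domain_segment(rng, tet, n_ctx)
                        planted.append((pos, pos + len(seg), pos + hepta_off, tet, n_ctx))
                        chunks.append(seg)
                        pos += len(seg)
                    else:
                        span = _ACCESSORY_SPAN[tok]
                        seg = _draw_residues(rng, span, alphabet, weights)
                        acc_spans.append((tok, pos, pos + span))
                        chunks.append(seg)
                        pos += span
                    gap = bg()
                    chunks.append(gap)
                    pos += len(gap)

                seq = list("".join(chunks))
                hepta_starts = {h for (_, _, h, _, _) in planted}
                _sanitize_background(seq, hepta_starts, rng)

                # within-domain mutation, after sanitizing: planted truth keeps
                # the pre-mutation strings, so recall may drop below 1
                if spec.mutation_rate > 0:
                    for (dstart, dend, _, _, _) in planted:
                        for i in range(dstart, dend):
                            if rng.random() < spec.mutation_rate:
                                seq[i] = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]

                sequence = "".join(seq)
                domains = []
                for i, (dstart, dend, hepta, tet, _) in enumerate(planted):
                    if len(planted) == 1:
                        term = Terminal.SINGLE_C
                    elif i == 0:
                        term = Terminal.N_TERMINAL
                    elif i == len(planted) - 1:
                        term = Terminal.C_TERMINAL
                    else:
                        term = Terminal.INTERNAL
                    domains.append(
                        PlantedDomain(
                            start=dstart,
                            end=dend,
                            hepta_start=hepta,
                            tetramer=tet,
                            tail=CANONICAL_TAIL,
                            variant_class=(
                                VariantClass.CANONICAL
                                if tet == CANONICAL_TETRAMER
                                else VariantClass.VARIANT
                            ),
                            terminal=term,
                        )
                    )
                records.append(
                    ProteinRecord(
                        id=pid,
                        sequence=sequence,
                        genus=genus,
                        species_epithet=epithet,
                        source_note="synthetic",
                    )
                )
                for name, a, b in acc_spans:
                    accessories.append(
                        AccessoryDomainHit(
                            protein_id=pid,
                            name=AccessoryDomain[name],
                            start=a,
                            end=b,
                        )
                    )
                truth.proteins[pid] = ProteinTruth(
                    protein_id=pid,
                    species=species,
                    family_number=fam,
                    domains=domains,
                    architecture=arch,
                )
    return records, accessories, truth


# ---------------------------------------------------------------------------
# labelled families for grouping

def mutate_sequence(seq: str, p: float, rng: np.random.Generator) -> str:
    """Per-site substitution with probability ``p``, to one of the 19
    other residues."""
    out = list(seq)
    for i, ch in enumerate(out):
        if rng.random() < p:
            choices = AMINO_ACIDS.replace(ch, "")
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


_ROMANS = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


def generate_labeled_families(
    n_groups: int,
    per_group_divergence: float,
    between_group_divergence: float,
    n_per_group: int = 8,
    n_refs_per_group: int = 2,
    seq_length: int = 200,
    families_per_group: int = 2,
    seed: int = 0,
) -> tuple[AlignedBlock, dict[str, str], dict[str, str], dict[str, int]]:
    """Clade-structured aligned families with reference labels.

    Each group descends from its own ancestor (derived from a common root
    at ``between_group_divergence``); members diverge from the group
    ancestor at ``per_group_divergence``. Indel-free, so rows are already
    aligned. Returns (alignment, reference labels, true group per leaf,
    family number per leaf). Family numbers are partitioned between
    groups, so perfect grouping yields no overlap flags.
    """
    if n_groups < 2 or n_groups > len(_ROMANS):
        raise ValueError("n_groups out of supported range")
    if n_per_group <= n_refs_per_group:
        raise ValueError("need more members than references per group")
    rng = np.random.default_rng(seed)
    root = _draw_residues(rng, seq_length)
    ids: list[str] = []
    rows: list[str] = []
    reference_labels: dict[str, str] = {}
    true_groups: dict[str, str] = {}
    family_numbers: dict[str, int] = {}
    for g in range(n_groups):
        label = _ROMANS[g]
        ancestor = mutate_sequence(root, between_group_divergence, rng)
        for m in range(n_per_group):
            member = mutate_sequence(ancestor, per_group_divergence, rng)
            is_ref = m < n_refs_per_group
            name = f"{'ref' if is_ref else 'query'}_{label}_{m}"
            ids.append(name)
            rows.append(member)
            true_groups[name] = label
            family_numbers[name] = g * families_per_group + (m % families_per_group) + 1
            if is_ref:
                reference_labels[name] = label
    return AlignedBlock(ids=ids, rows=rows), reference_labels, true_groups, family_numbers


# ---------------------------------------------------------------------------
# triplets

def generate_triplet(
    rate_A: float,
    rate_B: float,
    rate_C: float,
    n_sites: int,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, int]]:
    """Three aligned sequences from a common random ancestor.

    Independent-site substitutions: each branch applies the equal-rate
    20-state process at its branch length (expected substitutions per
    site). Returns the sequences keyed "A", "B", "C" and the realized
    per-branch substituted-site counts.
    """
    if min(rate_A, rate_B, rate_C) < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    ancestor = rng.integers(0, 20, size=n_sites)
    from .ratetest import _evolve

    seqs = {}
    realized = {}
    for name, rate in (("A", rate_A), ("B", rate_B), ("C", rate_C)):
        end = _evolve(rng, ancestor, rate)
        seqs[name] = "".join(AMINO_ACIDS[i] for i in end)
        realized[name] = int((end != ancestor).sum())
    return seqs, realized


# ---------------------------------------------------------------------------
# reference panel for nomenclature

def make_reference_panel(
    n_per_lineage: int = 75, seed: int = 716245,
) -> list[ReferenceEntry]:
    """Synthetic reference panel: distinguishable WRKY domain sequences
    for reference numbers 1..n per lineage.

    Stands in for the Arabidopsis (dicot) and rice (monocot) reference
    domain sets; sequences share the canonical heptapeptide and zinc
    finger but differ in their variable positions.
    """
    rng = np.random.default_rng(seed)
    entries = []
    for lineage, prefix in ((Lineage.DICOT_REF, "AtWRKY"), (Lineage.MONOCOT_REF, "OsWRKY")):
        for num in range(1, n_per_lineage + 1):
            seg, _, _ = _domain_segment(rng, CANONICAL_TETRAMER, n_context=False)
            tail_pad = _draw_residues(rng, 8)
            entries.append(
                ReferenceEntry(
                    reference_name=f"{prefix}{num}",
                    lineage=lineage,
                    domain_sequence=seg + tail_pad,
                )
            )
    return entries


def write_reference_panel(entries: Sequence[ReferenceEntry], path) -> None:
    with open(path, "w") as fh:
        fh.write("# synthetic reference panel (generated domain sequences)\n")
        fh.write("name\tlineage\tdomain_sequence\n")
        for e in entries:
            fh.write(f"{e.reference_name}\t{e.lineage.value}\t{e.domain_sequence}\n")
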