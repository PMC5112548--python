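"""WRKY domain calling on raw protein sequences.

A WRKY domain is recognized by two features: the heptapeptide signature
(canonical WRKYGQK, or a catalogued variant of its WRKY tetramer slot)
and a downstream C2H2/C2HC zinc finger. The heptapeptide is scanned as a
4-residue tetramer (the WRKY slot) followed by a 3-residue tail (the GQK
slot, matched within a configurable Hamming distance). The zinc finger
is matched as C-x(4..7)-C-x(21..26)-H-x(1..2)-[H|C]; the spacer ranges
are configurable because the conserved-block spacings reported for this
family differ between single- and double-domain proteins (x4/x5/x7 for
the first spacer, x22/x23/x26 for the second).

A non-canonical tetramer counts as a variant hit only when both its
GQK-like tail and a zinc finger within the search window corroborate it;
this suppresses spurious 4-mer matches in unconstrained sequence.
Heptapeptides with a canonical WRKY tetramer are retained even when no
intact finger is found (the finger is then recorded as absent), since
truncated family members lacking an intact finger do occur.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .core_io import ProteinRecord

CANONICAL_TETRAMER = "WRKY"
CANONICAL_TAIL = "GQK"

#: The 28 accepted substitutions of the WRKY tetramer slot. Each is a
#: 4-mer observed aligned exactly to the canonical WRKY position in
#: family-wide alignments.
VARIANT_TETRAMERS = frozenset(
    {
        # long-known substitutes
        "WRRY", "WSKY", "WKRY", "WVKY", "WKKY",
        # substitutes recovered from family-wide alignments
        "WRIY", "WRKN", "WRKD", "WHQY", "WRIS", "WRQV", "GRKY", "WLKY",
        "WREY", "ARKM", "WWKN", "WRMY", "WRKR", "WIKY", "WQKY", "WHKC",
        "WRCI", "FRKY", "RSQY", "WTKY", "WKKC", "WRKC",
        # C-terminal-region substitute
        "WWKS",
    }
)


class VariantClass(Enum):
    CANONICAL = "canonical"
    VARIANT = "variant"
    NONCANONICAL_TAIL = "noncanonical_tail"


class ZincFingerType(Enum):
    C2H2 = "C2H2"
    C2HC = "C2HC"


class Terminal(Enum):
    SINGLE_C = "single_c"
    N_TERMINAL = "n_terminal"
    C_TERMINAL = "c_terminal"
    INTERNAL = "internal"


@dataclass(frozen=True)
class HeptapeptideHit:
    start: int  # 0-based position of the tetramer
    tetramer: str
    tail: str
    variant_class: VariantClass

    @property
    def tail_mismatch(self) -> int:
        return _hamming(self.tail, CANONICAL_TAIL)

    @property
    def end(self) -> int:
        return self.start + 7


@dataclass(frozen=True)
class ZincFingerHit:
    positions: tuple[int, int, int, int]  # the four coordinating residues
    zf_type: ZincFingerType
    spacer_pattern: str

    @property
    def start(self) -> int:
        return self.positions[0]

    @property
    def end(self) -> int:
        return self.positions[3] + 1


@dataclass(frozen=True)
class WRKYDomainHit:
    protein_id: str
    start: int  # 0-based half-open domain interval
    end: int
    heptapeptide: HeptapeptideHit
    zinc_finger: Optional[ZincFingerHit]
    terminal: Terminal

    def overlaps(self, other: "WRKYDomainHit") -> bool:
        return self.start < other.end and other.start < self.end


def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(x != y for x, y in zip(a, b))


def scan_heptapeptide(
    sequence: str, tail_mismatch: int = 1
) -> list[HeptapeptideHit]:
    """Report every heptapeptide signature in ascending start order.

    A position qualifies when its 4-mer is the canonical WRKY tetramer or
    a catalogued variant, and the following 3-mer is within ``tail_mismatch``
    Hamming distance of GQK. X never matches any motif position.
    """
    hits = []
    for i in range(len(sequence) - 6):
        tet = sequence[i : i + 4]
        if tet != CANONICAL_TETRAMER and tet not in VARIANT_TETRAMERS:
            continue
        tail = sequence[i + 4 : i + 7]
        if _hamming(tail, CANONICAL_TAIL) > tail_mismatch:
            continue
        if tet == CANONICAL_TETRAMER:
            vclass = (
                VariantClass.CANONICAL
                if tail == CANONICAL_TAIL
                else VariantClass.NONCANONICAL_TAIL
            )
        else:
            vclass = VariantClass.VARIANT
        hits.append(HeptapeptideHit(start=i, tetramer=tet, tail=tail, variant_class=vclass))
    return hits


def _zf_regex(cc: tuple[int, int], ch: tuple[int, int], hh: tuple[int, int]) -> re.Pattern:
    return re.compile(
        rf"(C).{{{cc[0]},{cc[1]}}}?(C).{{{ch[0]},{ch[1]}}}?(H).{{{hh[0]},{hh[1]}}}?([HC])"
    )


def scan_zinc_finger(
    sequence: str,
    from_position: int = 0,
    window: int = 120,
    cc_spacer: tuple[int, int] = (4, 7),
    ch_spacer: tuple[int, int] = (21, 26),
    hh_spacer: tuple[int, int] = (1, 2),
) -> Optional[ZincFingerHit]:
    """Earliest C2H2/C2HC zinc finger at or after ``from_position``.

    Lazy quantifiers make the leftmost match also use the shortest
    spacers consistent with the configured ranges. Returns None when no
    finger lies within ``window`` residues of ``from_position``.
    """
    if from_position < 0 or from_position > len(sequence):
        raise ValueError("from_position outside sequence")
    segment = sequence[from_position : from_position + window]
    m = _zf_regex(cc_spacer, ch_spacer, hh_spacer).search(segment)
    if m is None:
        return None
    positions = tuple(from_position + m.start(g) for g in range(1, 5))
    zf_type = ZincFingerType.C2H2 if m.group(4) == "H" else ZincFingerType.C2HC
    spacers = (
        positions[1] - positions[0] - 1,
        positions[2] - positions[1] - 1,
        positions[3] - positions[2] - 1,
    )
    return ZincFingerHit(
        positions=positions,
        zf_type=zf_type,
        spacer_pattern=render_zf_pattern(spacers, zf_type),
    )


def render_zf_pattern(spacers: tuple[int, int, int], zf_type: ZincFingerType) -> str:
    """Canonical rendering like ``C-x4-C-x23-H-x-H`` (a spacer of 1 is ``x``)."""
    def x(n: int) -> str:
        return "x" if n == 1 else f"x{n}"

    last = "H" if zf_type is ZincFingerType.C2H2 else "C"
    return f"C-{x(spacers[0])}-C-{x(spacers[1])}-H-{x(spacers[2])}-{last}"


_ZF_PATTERN_RE = re.compile(r"C-x(\d*)-C-x(\d*)-H-x(\d*)-([HC])$")


def parse_zf_pattern(pattern: str) -> tuple[int, int, int, str]:
    """Inverse of :func:`render_zf_pattern`: spacers plus final residue."""
    m = _ZF_PATTERN_RE.match(pattern)
    if m is None:
        raise ValueError(f"not a zinc-finger spacer pattern: {pattern!r}")
    a, b, c, last = m.groups()
    return (int(a or 1), int(b or 1), int(c or 1), last)


def describe_zf_pattern(hit: ZincFingerHit) -> str:
    return hit.spacer_pattern


#: residues of upstream context included in the domain interval (covers the
#: conserved D-G-Y-N/R block preceding the heptapeptide)
DOMAIN_UPSTREAM = 10
#: domain extent used when no zinc finger is found (~60 aa total)
DOMAIN_FALLBACK_SPAN = 50


def call_domains(
    protein: ProteinRecord,
    tail_mismatch: int = 1,
    zf_window: int = 120,
    cc_spacer: tuple[int, int] = (4, 7),
    ch_spacer: tuple[int, int] = (21, 26),
    hh_spacer: tuple[int, int] = (1, 2),
) -> list[WRKYDomainHit]:
    """Call WRKY domains on one protein.

    Heptapeptide hits are paired with their nearest downstream zinc
    finger. Variant-tetramer candidates require both a GQK-like tail and
    a corroborating finger; canonical-tetramer candidates survive without
    a finger. Overlapping candidates are resolved by preferring canonical
    tetramers, then smaller tail mismatch, then the leftmost start. The
    domain interval runs from ``DOMAIN_UPSTREAM`` residues before the
    heptapeptide to the last zinc-finger residue, truncated at sequence
    bounds.
    """
    seq = protein.sequence
    candidates: list[WRKYDomainHit] = []
    for hepta in scan_heptapeptide(seq, tail_mismatch=tail_mismatch):
        zf = scan_zinc_finger(
            seq,
            from_position=hepta.end,
            window=zf_window,
            cc_spacer=cc_spacer,
            ch_spacer=ch_spacer,
            hh_spacer=hh_spacer,
        )
        if zf is None and hepta.tetramer != CANONICAL_TETRAMER:
            continue  # variant gating: uncorroborated variant tetramer
        start = max(0, hepta.start - DOMAIN_UPSTREAM)
        end = zf.end if zf is not None else min(len(seq), hepta.start + DOMAIN_FALLBACK_SPAN)
        candidates.append(
            WRKYDomainHit(
                protein_id=protein.id,
                start=start,
                end=end,
                heptapeptide=hepta,
                zinc_finger=zf,
                terminal=Terminal.SINGLE_C,  # finalized below
            )
        )

    # overlap resolution: canonical > non-canonical, then smaller tail
    # mismatch, then leftmost
    def priority(hit: WRKYDomainHit):
        return (
            hit.heptapeptide.variant_class is not VariantClass.CANONICAL,
            hit.heptapeptide.tail_mismatch,
            hit.heptapeptide.start,
        )

    accepted: list[WRKYDomainHit] = []
    for cand in sorted(candidates, key=priority):
        if not any(cand.overlaps(a) for a in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda h: h.start)

    n = len(accepted)
    final = []
    for i, hit in enumerate(accepted):
        if n == 1:
            term = Terminal.SINGLE_C
        elif i == 0:
            term = Terminal.N_TERMINAL
        elif i == n - 1:
            term = Terminal.C_TERMINAL
        else:
            term = Terminal.INTERNAL
        final.append(
            WRKYDomainHit(
                protein_id=hit.protein_id,
                start=hit.start,
                end=hit.end,
                heptapeptide=hit.heptapeptide,
                zinc_finger=hit.zinc_finger,
                terminal=term,
            )
        )
    return final
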