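"""Classification of ordered domain content into architecture classes.

Beyond the classic single- and double-domain forms, WRKY proteins occur
as chimeras fusing the DNA-binding domain with kinase, TIR, LRR, NAC,
B3, CBS, ZF_SBP, PAH, ULP-protease or ATP-GRASP domains. Each protein's
hits (WRKY calls plus accessory-domain intervals) are ordered by start
coordinate, run-length encoded, and matched against a closed set of
chimera templates; the most specific (longest) template wins, with a
fixed template order breaking ties. Proteins matching no template are
labelled by WRKY-domain count alone, or CHIMERIC_OTHER when they carry
accessory domains in an unrecognized arrangement.

Accessory domains are consumed as an interval table produced upstream
(by any scanner, or by the synthetic generator); they are not detected
de novo here, which keeps the classifier testable and tool-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .core_io import ProteinRecord
from .motif_scan import WRKYDomainHit


class AccessoryDomain(Enum):
    KINASE = "KINASE"
    TIR = "TIR"
    LRR = "LRR"
    NAC = "NAC"
    B3 = "B3"
    CBS = "CBS"
    ZF_SBP = "ZF_SBP"
    PAH = "PAH"
    ULP_PROTEASE = "ULP_PROTEASE"
    ATP_GRASP = "ATP_GRASP"


@dataclass(frozen=True)
class AccessoryDomainHit:
    protein_id: str
    name: AccessoryDomain
    start: int  # 0-based half-open
    end: int


class ArchitectureClass(Enum):
    SINGLE_C = "single_wrky"
    DOUBLE_NC = "double_wrky"
    TRIPLE_WRKY = "triple_wrky"
    QUAD_WRKY = "quad_wrky"
    TRIPLE_WRKY_ZF_SBP = "triple_wrky_zf_sbp"
    WRKY_CBS3 = "wrky_three_cbs"
    KINASE_WRKY = "kinase_wrky"
    KINASE_DOUBLE_WRKY = "kinase_double_wrky"
    DOUBLE_WRKY_KINASE = "double_wrky_kinase"
    PAH_DOUBLE_WRKY_KINASE = "pah_double_wrky_kinase"
    PROTEASE_WRKY = "ulp_protease_wrky"
    TIR_WRKY = "tir_wrky"
    TIR_DOUBLE_WRKY = "tir_double_wrky"
    TIR_LRR_WRKY = "tir_lrr_wrky"
    LRR_NAC_DOUBLE_WRKY = "lrr_nac_double_wrky"
    ATP_GRASP_WRKY = "atp_grasp_wrky"
    B3_WRKY = "b3_wrky"
    WRKY_ZF_SBP = "wrky_zf_sbp"
    CHIMERIC_OTHER = "chimeric_other"


@dataclass
class ArchitectureCall:
    protein_id: str
    domain_string: str  # run-length encoded ordered tokens, e.g. "TIR,LRRx7,WRKY"
    wrky_count: int
    class_label: ArchitectureClass


@dataclass
class SpeciesSummary:
    species: str
    n_single: int
    n_double: int
    n_novel: int
    n_total: int


class NotAWRKYError(ValueError):
    """Raised for a protein without any WRKY domain call."""


WRKY_TOKEN = "WRKY"

# Chimera templates as (token, min_repeats, max_repeats) tuples, in the
# fixed order used for tie-breaking. LRR blocks match two or more repeats:
# repeat numbers are brittle across scanners, so the observed count is kept
# in the domain string rather than in the template.
_INF = 10**9
_TEMPLATES: list[tuple[ArchitectureClass, tuple[tuple[str, int, int], ...]]] = [
    (ArchitectureClass.TRIPLE_WRKY_ZF_SBP, ((WRKY_TOKEN, 3, 3), ("ZF_SBP", 1, 1))),
    (ArchitectureClass.WRKY_CBS3, ((WRKY_TOKEN, 1, 1), ("CBS", 3, 3))),
    (ArchitectureClass.KINASE_WRKY, (("KINASE", 1, 1), (WRKY_TOKEN, 1, 1))),
    (ArchitectureClass.KINASE_DOUBLE_WRKY, (("KINASE", 1, 1), (WRKY_TOKEN, 2, 2))),
    (ArchitectureClass.DOUBLE_WRKY_KINASE, ((WRKY_TOKEN, 2, 2), ("KINASE", 1, 1))),
    (
        ArchitectureClass.PAH_DOUBLE_WRKY_KINASE,
        (("PAH", 1, 1), (WRKY_TOKEN, 2, 2), ("KINASE", 1, 1)),
    ),
    (ArchitectureClass.PROTEASE_WRKY, (("ULP_PROTEASE", 1, 1), (WRKY_TOKEN, 1, 1))),
    (ArchitectureClass.TIR_WRKY, (("TIR", 1, 1), (WRKY_TOKEN, 1, 1))),
    (ArchitectureClass.TIR_DOUBLE_WRKY, (("TIR", 1, 1), (WRKY_TOKEN, 2, 2))),
    (
        ArchitectureClass.TIR_LRR_WRKY,
        (("TIR", 1, 1), ("LRR", 2, _INF), (WRKY_TOKEN, 1, 1)),
    ),
    (
        ArchitectureClass.LRR_NAC_DOUBLE_WRKY,
        (("LRR", 2, _INF), ("NAC", 1, 1), (WRKY_TOKEN, 2, 2)),
    ),
    (ArchitectureClass.ATP_GRASP_WRKY, (("ATP_GRASP", 1, 1), (WRKY_TOKEN, 1, 1))),
    (ArchitectureClass.B3_WRKY, (("B3", 1, 1), (WRKY_TOKEN, 1, 1))),
    (ArchitectureClass.WRKY_ZF_SBP, ((WRKY_TOKEN, 1, 1), ("ZF_SBP", 1, 1))),
]


def _run_length(tokens: Sequence[str]) -> list[tuple[str, int]]:
    runs: list[tuple[str, int]] = []
    for tok in tokens:
        if runs and runs[-1][0] == tok:
            runs[-1] = (tok, runs[-1][1] + 1)
        else:
            runs.append((tok, 1))
    return runs


def _matches(runs: list[tuple[str, int]], template) -> bool:
    if len(runs) != len(template):
        return False
    return all(
        tok == t_tok and t_min <= count <= t_max
        for (tok, count), (t_tok, t_min, t_max) in zip(runs, template)
    )


def _template_length(template) -> int:
    return sum(t_min for _, t_min, _ in template)


def classify_architecture(
    wrky_hits: Sequence[WRKYDomainHit],
    accessory_hits: Sequence[AccessoryDomainHit] = (),
) -> ArchitectureCall:
    """Classify one protein's ordered domain content.

    All hits must belong to the same protein. Tokens are ordered by start
    coordinate; adjacent repeats are run-length encoded in the domain
    string. Template matching is order-sensitive (a kinase before the
    WRKY domain is a different class than one after it).
    """
    if not wrky_hits:
        raise NotAWRKYError("protein has no WRKY domain call")
    pids = {h.protein_id for h in wrky_hits} | {a.protein_id for a in accessory_hits}
    if len(pids) != 1:
        raise ValueError(f"hits span multiple proteins: {sorted(pids)}")
    (protein_id,) = pids

    items: list[tuple[int, str]] = [(h.start, WRKY_TOKEN) for h in wrky_hits]
    items += [(a.start, a.name.value) for a in accessory_hits]
    items.sort()
    tokens = [tok for _, tok in items]
    runs = _run_length(tokens)
    domain_string = ",".join(
        tok if count == 1 else f"{tok}x{count}" for tok, count in runs
    )
    wrky_count = sum(1 for tok in tokens if tok == WRKY_TOKEN)

    matches = [
        (cls, template)
        for cls, template in _TEMPLATES
        if _matches(runs, template)
    ]
    if matches:
        # most specific (longest) template wins; ties by template order
        best = max(
            enumerate(matches),
            key=lambda im: (_template_length(im[1][1]), -im[0]),
        )
        label = best[1][0]
    elif accessory_hits:
        label = ArchitectureClass.CHIMERIC_OTHER
    elif wrky_count == 1:
        label = ArchitectureClass.SINGLE_C
    elif wrky_count == 2:
        label = ArchitectureClass.DOUBLE_NC
    elif wrky_count == 3:
        label = ArchitectureClass.TRIPLE_WRKY
    elif wrky_count == 4:
        label = ArchitectureClass.QUAD_WRKY
    else:
        label = ArchitectureClass.CHIMERIC_OTHER
    return ArchitectureCall(
        protein_id=protein_id,
        domain_string=domain_string,
        wrky_count=wrky_count,
        class_label=label,
    )


_PLAIN_CLASSES = {ArchitectureClass.SINGLE_C, ArchitectureClass.DOUBLE_NC}


def summarize_species(
    calls: Iterable[ArchitectureCall],
    proteins: Iterable[ProteinRecord],
) -> list[SpeciesSummary]:
    """Per-species counts of single, double and novel (all other) forms.

    ``n_total`` is the number of proteins with at least one WRKY domain,
    i.e. the number of architecture calls for the species. All four
    numbers are reported without forcing single+double+novel to equal the
    total, mirroring published census tables where the column semantics
    allow a protein to satisfy more than one column.
    """
    by_id = {p.id: p for p in proteins}
    buckets: dict[str, list[ArchitectureCall]] = {}
    for call in calls:
        if call.protein_id not in by_id:
            raise ValueError(f"call references unknown protein {call.protein_id!r}")
        sp = by_id[call.protein_id].species
        buckets.setdefault(sp, []).append(call)
    # species with records but no calls still get a zero row
    for p in by_id.values():
        buckets.setdefault(p.species, [])
    summaries = []
    for sp in sorted(buckets):
        calls_sp = buckets[sp]
        n_single = sum(1 for c in calls_sp if c.class_label is ArchitectureClass.SINGLE_C)
        n_double = sum(1 for c in calls_sp if c.class_label is ArchitectureClass.DOUBLE_NC)
        n_novel = sum(1 for c in calls_sp if c.class_label not in _PLAIN_CLASSES)
        summaries.append(
            SpeciesSummary(
                species=sp,
                n_single=n_single,
                n_double=n_double,
                n_novel=n_novel,
                n_total=len(calls_sp),
            )
        )
    return summaries


def write_architecture_table(calls: Iterable[ArchitectureCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tdomain_string\twrky_count\tclass_label\n")
        for c in calls:
            fh.write(
                f"{c.protein_id}\t{c.domain_string}\t{c.wrky_count}\t{c.class_label.name}\n"
            )


def read_accessory_table(path) -> list[AccessoryDomainHit]:
    """Read an accessory-domain interval TSV (1-based inclusive coordinates)."""
    hits = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#") and ln.strip()]
    header = lines[0].split("\t") if lines else []
    if header != ["protein_id", "name", "start", "end"]:
        raise ValueError(f"unexpected accessory-table header in {path}")
    for ln in lines[1:]:
        pid, name, start, end = ln.split("\t")
        hits.append(
            AccessoryDomainHit(
                protein_id=pid,
                name=AccessoryDomain[name],
                start=int(start) - 1,
                end=int(end),
            )
        )
    return hits


def write_accessory_table(hits: Iterable[AccessoryDomainHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        fh.write("protein_id\tname\tstart\tend\n")
        for h in hits:
            fh.write(f"{h.protein_id}\t{h.name.value}\t{h.start + 1}\t{h.end}\n")
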