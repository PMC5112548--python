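"""Species prefixes, orthology assignment, paralog numbering."""

import numpy as np
import pytest

from wrkykit.nomenclature import (
    Lineage,
    NameAssignment,
    PrefixCollisionError,
    assign_orthology,
    number_paralogs,
    packaged_references,
    species_prefix,
)
from wrkykit.synthetic_data import make_reference_panel, mutate_sequence


@pytest.mark.parametrize(
    "genus,epithet,taken,expected",
    [
        ("Arabidopsis", "thaliana", set(), "At"),
        ("Phaseolus", "vulgaris", {"Pv"}, "Pvul"),
        ("Chlamydomonas", "reinhardtii", {"Cr"}, "Crein"),
        ("Prunus", "persica", {"Pp"}, "Pper"),
        ("Cucumis", "sativus", {"Cs"}, "Csa"),
    ],
)
def test_prefix_examples(genus, epithet, taken, expected):
    assert species_prefix(genus, epithet, taken) == expected
    assert expected in taken  # registered


def test_prefix_collision_exhaustion():
    taken = {"Aa", "Aab", "Aabc", "Aabca"}
    with pytest.raises(PrefixCollisionError):
        species_prefix("Aardvark", "abcabc", taken)


def test_prefix_requires_alphabetic_input():
    with pytest.raises(ValueError):
        species_prefix("X1", "thaliana", set())


# the species census, in its published order, with the abbreviations the
# prefix algorithm must reproduce for the distinctions that matter
SPECIES_CENSUS = [
    ("Aquilegia", "coerulea", "Ac"),
    ("Arabidopsis", "lyrata", "Al"),
    ("Arabidopsis", "thaliana", "At"),
    ("Brachypodium", "distachyon", "Bd"),
    ("Brassica", "rapa", "Br"),
    ("Capsella", "rubella", "Cr"),
    ("Carica", "papaya", "Cp"),
    ("Chlamydomonas", "reinhardtii", "Crein"),
    ("Citrus", "clementina", "Cc"),
    ("Citrus", "sinensis", "Cs"),
    ("Coccomyxa", "subellipsoidea", None),
    ("Cucumis", "sativus", "Csa"),
    ("Dictyostelium", "purpureum", "Dp"),
    ("Eucalyptus", "grandis", "Eg"),
    ("Fragaria", "vesca", "Fv"),
    ("Glycine", "max", "Gm"),
    ("Gossypium", "raimondii", "Gr"),
    ("Linum", "usitatissimum", "Lu"),
    ("Malus", "domestica", "Md"),
    ("Manihot", "esculenta", "Me"),
    ("Medicago", "truncatula", "Mt"),
    ("Micromonas", "pusilla", "Mp"),
    ("Mimulus", "guttatus", "Mg"),
    ("Oryza", "sativa", "Os"),
    ("Ostreococcus", "lucimarinus", "Ol"),
    ("Panicum", "hallii", "Ph"),
    ("Panicum", "virgatum", "Pv"),
    ("Phaseolus", "vulgaris", "Pvul"),
    ("Physcomitrella", "patens", "Pp"),
    ("Picea", "abies", "Pa"),
    ("Populus", "trichocarpa", "Pt"),
    ("Prunus", "persica", "Pper"),
    ("Ricinus", "communis", "Rc"),
    ("Selaginella", "moellendorffii", "Sm"),
    ("Setaria", "italica", "Si"),
    ("Solanum", "lycopersicum", "Sl"),
    ("Solanum", "tuberosum", "St"),
    ("Sorghum", "bicolor", "Sb"),
    ("Thellungiella", "halophila", "Th"),
    ("Theobroma", "cacao", "Tc"),
    ("Vitis", "vinifera", "Vv"),
    ("Volvox", "carteri", "Vc"),
    ("Zea", "mays", "Zm"),
]


def test_census_order_prefixes_unique_and_expected():
    taken: set[str] = set()
    got = [species_prefix(g, e, taken) for g, e, _ in SPECIES_CENSUS]
    assert len(set(got)) == len(got)
    for (g, e, expected), prefix in zip(SPECIES_CENSUS, got):
        if expected is not None:
            assert prefix == expected, f"{g} {e}: {prefix} != {expected}"


# ---------------------------------------------------------------------------
# orthology

def test_self_match_is_maximal():
    refs = packaged_references()
    target = next(r for r in refs if r.reference_name == "AtWRKY33")
    best, _ = assign_orthology(target.domain_sequence, refs, Lineage.DICOT_REF)
    assert best.reference_name == "AtWRKY33"


def test_two_substitutions_still_recover_reference():
    refs = [r for r in packaged_references() if r.reference_name in ("AtWRKY33", "AtWRKY70")]
    target = next(r for r in refs if r.reference_name == "AtWRKY33")
    q = list(target.domain_sequence)
    q[5] = "A" if q[5] != "A" else "G"
    q[20] = "A" if q[20] != "A" else "G"
    best, score = assign_orthology("".join(q), refs, Lineage.DICOT_REF)
    assert best.reference_name == "AtWRKY33"
    # exhaustive check over the 2-entry set: the other reference scores lower
    other = next(r for r in refs if r.reference_name == "AtWRKY70")
    _, other_score = assign_orthology("".join(q), [other], Lineage.DICOT_REF)
    assert score > other_score


def test_assignment_invariant_to_reference_order():
    refs = packaged_references()
    rng = np.random.default_rng(3)
    query = mutate_sequence(refs[7].domain_sequence, 0.1, rng)
    a, _ = assign_orthology(query, refs, Lineage.DICOT_REF)
    b, _ = assign_orthology(query, list(reversed(refs)), Lineage.DICOT_REF)
    assert a.reference_name == b.reference_name


def test_lineage_filters_reference_pool():
    refs = packaged_references()
    best, _ = assign_orthology(refs[0].domain_sequence, refs, Lineage.MONOCOT_REF)
    assert best.reference_name.startswith("OsWRKY")
    with pytest.raises(ValueError, match="no references"):
        assign_orthology("WRKYGQK", [refs[0]], Lineage.MONOCOT_REF)


def test_reference_recovery_at_ten_percent_divergence():
    """Families evolved from labelled references are mapped back correctly."""
    refs = packaged_references()
    dicots = [r for r in refs if r.lineage is Lineage.DICOT_REF]
    rng = np.random.default_rng(42)
    correct = 0
    n_families = 100
    for i in range(n_families):
        truth = dicots[int(rng.integers(len(dicots)))]
        query = mutate_sequence(truth.domain_sequence, 0.10, rng)
        best, _ = assign_orthology(query, refs, Lineage.DICOT_REF)
        correct += best.reference_name == truth.reference_name
    assert correct / n_families >= 0.95


# ---------------------------------------------------------------------------
# paralog numbering

def _assignment(qid, number, prefix="Os"):
    return NameAssignment(query_id=qid, prefix=prefix, wrky_number=number, score=100.0)


def test_two_paralogs_get_hyphenated_indices():
    named = number_paralogs([_assignment("q1", 46), _assignment("q2", 46)])
    assert sorted(a.final_name for a in named) == ["OsWRKY46-1", "OsWRKY46-2"]


def test_singleton_gets_no_suffix():
    (named,) = number_paralogs([_assignment("q1", 7)])
    assert named.final_name == "OsWRKY7"
    assert named.paralog_index is None


def test_numbering_is_idempotent():
    once = number_paralogs([_assignment("q1", 46), _assignment("q2", 46)])
    twice = number_paralogs(once)
    assert once == twice


def test_suffix_density_no_gaps():
    named = number_paralogs([_assignment(f"q{i}", 12) for i in range(5)])
    assert sorted(a.paralog_index for a in named) == [1, 2, 3, 4, 5]


def test_coordinates_order_paralogs():
    named = number_paralogs(
        [_assignment("late", 46), _assignment("early", 46)],
        coordinates={"late": 2000.0, "early": 100.0},
    )
    by_id = {a.query_id: a.final_name for a in named}
    assert by_id == {"early": "OsWRKY46-1", "late": "OsWRKY46-2"}


def test_names_unique_within_species():
    named = number_paralogs(
        [_assignment("a", 5), _assignment("b", 5), _assignment("c", 9)]
    )
    names = [a.final_name for a in named]
    assert len(set(names)) == len(names)
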