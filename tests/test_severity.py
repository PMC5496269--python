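"""Knowledge base content and the diallelic combination rules."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from saamp import (
    MutationClass,
    Phenotype,
    Severity,
    combine_alleles,
    combine_atomic,
    kb_category_counts,
    predict_phenotype,
)
from saamp.severity import kb_lookup

S = Severity
P = Phenotype

#: independent statement of the four rules over all atomic pairs
EXPECTED_ATOMIC = {
    (S.SEVERE, S.SEVERE): {P.HURLER},
    (S.MILD, S.SEVERE): {P.SCHEIE},
    (S.INTERMEDIATE, S.SEVERE): {P.HURLER_SCHEIE},
    (S.INTERMEDIATE, S.INTERMEDIATE): {P.HURLER_SCHEIE, P.SCHEIE},
    (S.MILD, S.MILD): {P.SCHEIE},
    (S.MILD, S.INTERMEDIATE): {P.SCHEIE},  # any-mild rule overrides
    (S.UNKNOWN, S.UNKNOWN): {P.UNKNOWN},
    (S.UNKNOWN, S.MILD): {P.UNKNOWN},
    (S.UNKNOWN, S.INTERMEDIATE): {P.UNKNOWN},
    (S.UNKNOWN, S.SEVERE): {P.UNKNOWN},
}


def test_atomic_rules_exhaustive_and_symmetric():
    for a, b in itertools.product(list(S), repeat=2):
        expected = EXPECTED_ATOMIC.get((a, b)) or EXPECTED_ATOMIC[(b, a)]
        assert combine_atomic(a, b) == frozenset(expected), (a, b)
        assert combine_atomic(a, b) == combine_atomic(b, a)


def test_mild_branch_of_rule_two_agrees_with_any_mild_rule():
    assert combine_atomic(S.MILD, S.SEVERE) == frozenset({P.SCHEIE})


severity_sets = st.sets(
    st.sampled_from([S.MILD, S.INTERMEDIATE, S.SEVERE]), min_size=1, max_size=3
).map(frozenset) | st.just(frozenset({S.UNKNOWN}))


@settings(derandomize=True, max_examples=120)
@given(a=severity_sets, b=severity_sets)
def test_set_valued_combination_is_cartesian_closure(a, b):
    call = combine_alleles(a, b)
    brute = set()
    for sa in a:
        for sb in b:
            brute |= combine_atomic(sa, sb)
    assert call.phenotypes == frozenset(brute)
    assert combine_alleles(b, a).phenotypes == call.phenotypes  # symmetry


def test_set_valued_example():
    call = combine_alleles(frozenset({S.MILD, S.INTERMEDIATE}), frozenset({S.SEVERE}))
    assert call.phenotypes == frozenset({P.SCHEIE, P.HURLER_SCHEIE})


def test_empty_severity_set_rejected():
    with pytest.raises(ValueError):
        combine_alleles(frozenset(), frozenset({S.MILD}))


# ---------------------------------------------------------------- knowledge base

def test_kb_lookups(kb):
    assert kb["W402X"].severities == frozenset({S.SEVERE})
    assert kb["P533R"].severities == frozenset({S.UNKNOWN})
    assert kb["R89Q"].severities == frozenset({S.MILD, S.INTERMEDIATE})
    assert kb["396insAC"].severities == frozenset({S.MILD})
    assert kb["396insAC"].low_reliability is True
    assert kb["IVS4-1G>A"].severities == frozenset({S.INTERMEDIATE, S.SEVERE})


def test_kb_category_counts(kb):
    counts = kb_category_counts(kb)
    assert counts["nonsense"] == 22
    assert counts["splicing"] == 32
    assert counts["deletion_insertion"] == 45
    # the printed missense/nonsense table carries 106 cells (84 missense);
    # the source prose claims 86 missense — the transcription is faithful
    # to the printed cells, so the total is 183
    assert counts["missense"] == 84
    assert counts["total"] == 183


def test_all_nonsense_entries_severe(kb):
    nonsense = [
        e for e in kb.values()
        if e.mutation.mutation_class is MutationClass.NONSENSE
    ]
    assert len(nonsense) == 22
    assert all(e.severities == frozenset({S.SEVERE}) for e in nonsense)


def test_exactly_one_splicing_entry_is_mild(kb):
    mild_splice = [
        name
        for name, e in kb.items()
        if e.mutation.mutation_class is MutationClass.SPLICING
        and e.severities == frozenset({S.MILD})
    ]
    assert mild_splice == ["IVS5-7G>A"]


def test_column_placement_class_overrides(kb):
    assert kb["3308del12"].mutation.mutation_class is MutationClass.SPLICING
    assert kb["c.1-2C>G"].mutation.mutation_class is MutationClass.SPLICING
    assert kb["D444/445"].mutation.mutation_class is MutationClass.DELETION_INSERTION
    for stop_loss in ("X654C", "X654G", "X654R"):
        assert kb[stop_loss].mutation.mutation_class is MutationClass.MISSENSE
    assert kb["M1T"].mutation.mutation_class is MutationClass.MISSENSE


def test_case_insensitive_fallback_warns(kb):
    with pytest.warns(UserWarning, match="case folding"):
        entry = kb_lookup(kb, "w402x")
    assert entry is not None and entry.severities == frozenset({S.SEVERE})


# ---------------------------------------------------------------- workflow

def test_predict_phenotype_two_severe_alleles(kb):
    call = predict_phenotype("W402X", "W402X", kb=kb)
    assert call.phenotypes == frozenset({P.HURLER})
    assert call.trace[0]["path"] == "knowledge_base"


def test_predict_phenotype_severe_plus_mild_splice(kb):
    call = predict_phenotype("W402X", "IVS5-7G>A", kb=kb)
    assert call.phenotypes == frozenset({P.SCHEIE})


def test_predict_phenotype_unknown_allele_propagates(kb):
    call = predict_phenotype("W402X", "A999999T", kb=kb)
    assert call.phenotypes == frozenset({P.UNKNOWN})
    assert call.trace[1]["path"] == "not in knowledge base, no scores"


def test_predict_phenotype_symmetric_in_allele_order(kb):
    a = predict_phenotype("R89Q", "W402X", kb=kb)
    b = predict_phenotype("W402X", "R89Q", kb=kb)
    assert a.phenotypes == b.phenotypes


def test_predict_phenotype_novel_allele_with_scores(kb, consensus_profiles):
    """A novel allele with an ensemble profile gets a pathogenic/benign call
    in the trace, but its severity (hence the phenotype) stays unknown."""
    novel = next(p for p in consensus_profiles if p.variant.normalized_name == "L114R")
    assert "L114R" not in kb
    call = predict_phenotype(
        "W402X", "L114R", profiles={"L114R": novel}, kb=kb
    )
    assert call.phenotypes == frozenset({P.UNKNOWN})
    assert call.trace[1]["path"] == "ensemble_score"
    assert call.trace[1]["classification"] == "pathogenic"


def test_predict_phenotype_rejects_empty_name(kb):
    with pytest.raises(ValueError):
        predict_phenotype("", "W402X", kb=kb)
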