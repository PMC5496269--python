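"""Pathogenic index, cutoff rules, benchmark evaluation."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import confusion_matrix

from saamp import (
    PathogenicIndex,
    classify,
    compute_pi,
    cutoff_sweep,
    evaluate,
)
from saamp.predictors import PredictorProfile, Tool, ToolCall
from saamp.scoring import min_damaging_count, round_display
from saamp.simulate import GeneratorConfig, generate_benchmark
from saamp.variants import parse_mutation_name


def _binary_profile(n_damaging, n_available=7, name="A1V"):
    words = {
        Tool.SIFT: ("deleterious", "tolerated"),
        Tool.POLYPHEN: ("probably_damaging", "benign"),
        Tool.IMUTANT: ("large_decrease", "neutral"),
        Tool.PROVEAN: ("deleterious", "neutral"),
        Tool.PANTHER: ("deleterious", "neutral"),
        Tool.SNPSGO: ("disease", "neutral"),
        Tool.PHDSNP: ("disease", "neutral"),
    }
    calls = {}
    for i, tool in enumerate(list(Tool)[:n_available]):
        calls[tool] = ToolCall(tool, label=words[tool][0 if i < n_damaging else 1])
    return PredictorProfile(variant=parse_mutation_name(name), calls=calls)


@pytest.mark.parametrize(
    "damaging, available, pi, display",
    [
        (7, 7, Fraction(1), 1.0),
        (3, 7, Fraction(3, 7), 0.43),
        (4, 7, Fraction(4, 7), 0.57),
        (0, 5, Fraction(0), 0.0),
        (1, 2, Fraction(1, 2), 0.5),
    ],
)
def test_pathogenic_index_values(damaging, available, pi, display):
    record = PathogenicIndex(damaging, available)
    assert record.pi == pi
    assert record.pi_display == display


def test_compute_pi_from_profile():
    record = compute_pi(_binary_profile(3))
    assert (record.damaging_count, record.available_count) == (3, 7)
    with pytest.raises(ValueError, match="no predictions"):
        compute_pi(PredictorProfile(variant=parse_mutation_name("A1V")))


@pytest.mark.parametrize(
    "damaging, cutoff, expected",
    [
        (3, 0.43, "pathogenic"),
        (2, 0.43, "benign"),
        (3, 0.57, "benign"),
        (4, 0.57, "pathogenic"),
        (3, "sensitive", "pathogenic"),
        (4, "specific", "pathogenic"),
        (5, 5, "pathogenic"),
    ],
)
def test_classification_cutoffs(damaging, cutoff, expected):
    assert classify(PathogenicIndex(damaging, 7), cutoff) == expected


def test_count_rule_equals_fraction_rule_exhaustively():
    """PI >= 3/7 iff damaging >= 3, over every possible count (0..7)."""
    for d in range(8):
        record = PathogenicIndex(d, 7)
        assert (classify(record, 0.43) == "pathogenic") == (record.pi >= Fraction(3, 7))
        assert (classify(record, 0.57) == "pathogenic") == (record.pi >= Fraction(4, 7))
    # the displayed decimal is a rounding, not the operative threshold
    assert Fraction(3, 7) < Fraction(43, 100)
    assert round_display(3 / 7) == 0.43


def test_partial_profiles_use_ceiling_rule():
    # ceil(3/7 * available)
    assert min_damaging_count("sensitive", 7) == 3
    assert min_damaging_count("sensitive", 5) == 3
    assert min_damaging_count("sensitive", 3) == 2
    assert min_damaging_count("specific", 7) == 4
    assert min_damaging_count("specific", 4) == 3
    with pytest.raises(ValueError):
        min_damaging_count(0.44, 7)
    with pytest.raises(ValueError):
        min_damaging_count(9, 7)


def test_evaluate_reproduces_published_style_metrics():
    """81 pathogenic with 76 recovered, 15 benign with 12 recovered
    gives the 94%/80% sensitivity/specificity pattern."""
    pairs = (
        [("pathogenic", "pathogenic")] * 76
        + [("benign", "pathogenic")] * 5
        + [("benign", "benign")] * 12
        + [("pathogenic", "benign")] * 3
    )
    result = evaluate(pairs)
    assert (result.tp, result.fn, result.tn, result.fp) == (76, 5, 12, 3)
    assert result.sensitivity_percent == 94.0
    assert result.specificity_percent == 80.0


def test_evaluate_edge_cases():
    perfect = evaluate([("pathogenic", "pathogenic"), ("benign", "benign")])
    assert perfect.sensitivity == 1.0 and perfect.specificity == 1.0

    no_benign = evaluate([("pathogenic", "pathogenic")])
    assert no_benign.specificity is None
    assert no_benign.specificity_percent is None

    with pytest.raises(ValueError):
        evaluate([("pathogenic", "maybe")])


def test_inverting_true_labels_swaps_error_types():
    rng = np.random.default_rng(7)
    calls = rng.choice(["pathogenic", "benign"], size=200)
    labels = rng.choice(["pathogenic", "benign"], size=200)
    flipped = np.where(labels == "pathogenic", "benign", "pathogenic")
    a = evaluate(list(zip(calls, labels)))
    b = evaluate(list(zip(calls, flipped)))
    assert b.sensitivity == 1 - a.specificity
    assert b.specificity == 1 - a.sensitivity


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=60))
def test_evaluate_matches_sklearn_confusion_matrix(bits):
    pairs = [
        ("pathogenic" if c else "benign", "pathogenic" if t else "benign")
        for c, t in bits
    ]
    result = evaluate(pairs)
    y_pred = [p for p, _ in pairs]
    y_true = [t for _, t in pairs]
    tn, fp, fn, tp = confusion_matrix(
        y_true, y_pred, labels=["benign", "pathogenic"]
    ).ravel()
    assert (result.tp, result.fp, result.tn, result.fn) == (tp, fp, tn, fn)


def test_cutoff_sweep_monotone_and_noiseless():
    cfg = GeneratorConfig(n_pathogenic=81, n_benign=15,
                          tool_sensitivity=1.0, tool_specificity=1.0, seed=3)
    profiles, labels = generate_benchmark(cfg)
    results = cutoff_sweep(list(zip(profiles, labels)))
    assert len(results) == 7
    assert all(r.sensitivity == 1.0 for r in results)
    assert all(r.specificity == 1.0 for r in results)

    noisy_cfg = GeneratorConfig(n_pathogenic=300, n_benign=300, seed=11)
    profiles, labels = generate_benchmark(noisy_cfg)
    results = cutoff_sweep(list(zip(profiles, labels)))
    sens = [r.sensitivity for r in results]
    spec = [r.specificity for r in results]
    assert sens == sorted(sens, reverse=True)
    assert spec == sorted(spec)
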