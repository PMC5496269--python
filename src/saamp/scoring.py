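"""SAAMP: the ensemble pathogenic index and its benchmark evaluation.

The pathogenic index (PI) of a variant is the fraction of "damaging" calls
among the ensemble tools with a prediction available (up to 7).  A variant
is classified *pathogenic* when its PI clears a cutoff.  The two published
operating points are stated as decimals but defined operationally on
counts out of seven:

* sensitive cutoff, displayed 0.43 == at least 3 of 7 damaging calls
  (3/7 = 0.4286 rounds to 0.43);
* specific cutoff, displayed 0.57 == at least 4 of 7 damaging calls.

Classification is therefore implemented as an exact integer count rule,
``damaging_count >= ceil(cutoff_fraction * available_count)``, never as a
floating-point comparison against the rounded decimal (3/7 < 0.43 would
otherwise misclassify the boundary).  With all 7 tools available this
reduces to >= 3 and >= 4 respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .predictors import PredictorProfile

__all__ = [
    "PathogenicIndex",
    "BenchmarkResult",
    "compute_pi",
    "classify",
    "evaluate",
    "cutoff_sweep",
    "SENSITIVE_CUTOFF",
    "SPECIFIC_CUTOFF",
]

#: exact fractions behind the displayed decimal cutoffs
SENSITIVE_CUTOFF = Fraction(3, 7)  # displayed 0.43
SPECIFIC_CUTOFF = Fraction(4, 7)  # displayed 0.57

_CUTOFF_ALIASES: Dict[Union[str, float], Fraction] = {
    0.43: SENSITIVE_CUTOFF,
    0.57: SPECIFIC_CUTOFF,
    "0.43": SENSITIVE_CUTOFF,
    "0.57": SPECIFIC_CUTOFF,
    "sensitive": SENSITIVE_CUTOFF,
    "specific": SPECIFIC_CUTOFF,
}


def round_display(value: float, ndigits: int = 2) -> float:
    """Round half-up to ``ndigits`` decimals (publication-style display)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PathogenicIndex:
    """Damaging-call tally for one variant."""

    damaging_count: int
    available_count: int

    def __post_init__(self):
        if not 1 <= self.available_count <= 7:
            raise ValueError("available_count must be 1-7")
        if not 0 <= self.damaging_count <= self.available_count:
            raise ValueError("damaging_count must be within 0..available_count")

    @property
    def pi(self) -> Fraction:
        """Exact PI as a fraction (damaging / available)."""
        return Fraction(self.damaging_count, self.available_count)

    @property
    def pi_display(self) -> float:
        """PI rounded half-up to two decimals (3/7 -> 0.43, 4/7 -> 0.57)."""
        return round_display(self.damaging_count / self.available_count)


def compute_pi(profile: PredictorProfile, mode: str = "labels") -> PathogenicIndex:
    """Tally damaging calls across the profile's available tools."""
    if profile.available_tools == 0:
        raise ValueError(f"no predictions available for {profile.identifier}")
    return PathogenicIndex(
        damaging_count=profile.damaging_count(mode),
        available_count=profile.available_tools,
    )


def min_damaging_count(
    cutoff: Union[str, float, int, Fraction], available_count: int
) -> int:
    """Integer count threshold k for a cutoff at a given number of tools.

    k = ceil(cutoff_fraction * available_count); an integer cutoff is taken
    as k directly.
    """
    if isinstance(cutoff, bool):
        raise ValueError("cutoff must be a fraction alias or an integer count")
    if isinstance(cutoff, int):
        if not 1 <= cutoff <= 7:
            raise ValueError("integer cutoff must be 1-7")
        return cutoff
    if isinstance(cutoff, Fraction):
        frac = cutoff
    else:
        try:
            frac = _CUTOFF_ALIASES[cutoff]
        except (KeyError, TypeError):
            raise ValueError(
                f"unknown cutoff {cutoff!r}: use 0.43, 0.57, 'sensitive', "
                f"'specific', an exact Fraction, or an integer count"
            ) from None
    return math.ceil(frac * available_count)


def classify(
    pi_record: PathogenicIndex,
    cutoff: Union[str, float, int, Fraction] = "sensitive",
) -> str:
    """'pathogenic' or 'benign' under the count form of the cutoff rule."""
    k = min_damaging_count(cutoff, pi_record.available_count)
    return "pathogenic" if pi_record.damaging_count >= k else "benign"


@dataclass(frozen=True)
class BenchmarkResult:
    """Confusion matrix and operating characteristics at one cutoff."""

    tp: int
    fp: int
    tn: int
    fn: int
    cutoff: str

    @property
    def sensitivity(self) -> Optional[float]:
        pos = self.tp + self.fn
        return None if pos == 0 else self.tp / pos

    @property
    def specificity(self) -> Optional[float]:
        neg = self.tn + self.fp
        return None if neg == 0 else self.tn / neg

    @property
    def sensitivity_percent(self) -> Optional[float]:
        """Sensitivity as a whole percent, rounded half-up ('94%' style)."""
        s = self.sensitivity
        return None if s is None else round_display(100 * s, 0)

    @property
    def specificity_percent(self) -> Optional[float]:
        s = self.specificity
        return None if s is None else round_display(100 * s, 0)

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "sensitivity_percent": self.sensitivity_percent,
            "specificity_percent": self.specificity_percent,
        }


def evaluate(
    predictions: Sequence[Tuple[str, str]],
    cutoff: str = "",
) -> BenchmarkResult:
    """Tally (predicted, true) label pairs into a confusion matrix.

    Labels must be 'pathogenic' or 'benign'.  A metric whose denominator
    class is absent is reported as None (undefined), never 0.
    """
    tp = fp = tn = fn = 0
    for predicted, true in predictions:
        if true not in ("pathogenic", "benign"):
            raise ValueError(f"true label must be pathogenic/benign, got {true!r}")
        if predicted not in ("pathogenic", "benign"):
            raise ValueError(f"predicted label must be pathogenic/benign, got {predicted!r}")
        if true == "pathogenic":
            if predicted == "pathogenic":
                tp += 1
            else:
                fn += 1
        else:
            if predicted == "benign":
                tn += 1
            else:
                fp += 1
    return BenchmarkResult(tp=tp, fp=fp, tn=tn, fn=fn, cutoff=str(cutoff))


def cutoff_sweep(
    profiles_with_labels: Sequence[Tuple[PredictorProfile, str]],
    mode: str = "labels",
) -> List[BenchmarkResult]:
    """Benchmark at every integer count cutoff k = 1..7.

    Sensitivity is non-increasing and specificity non-decreasing in k.
    """
    pis = [(compute_pi(p, mode), label) for p, label in profiles_with_labels]
    results = []
    for k in range(1, 8):
        pairs = [(classify(pi, k), label) for pi, label in pis]
        results.append(evaluate(pairs, cutoff=f"k>={k}"))
    return results
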