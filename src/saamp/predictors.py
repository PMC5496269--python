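"""The seven ensemble predictors: numeric scores, categorical thresholds, profiles.

Each external tool publishes a score on its own scale together with a
categorical vocabulary:

========  =======================  ==========================================
tool      numeric scale            categories (damaging class first)
========  =======================  ==========================================
SIFT      tolerance index [0, 1]   deleterious (<= 0.05) / tolerated
PolyPhen  PSIC score [0, 1]        probably_damaging (> 0.85) /
                                   possibly_damaging (> 0.15) / benign
I-Mutant  DDG, kcal/mol            large_decrease (< -0.5) /
                                   large_increase (> 0.5) / neutral
PROVEAN   alignment score          deleterious (< -2.5) / neutral
PANTHER   subPSEC                  deleterious (< -3) / neutral
SNPs&GO   disease probability      disease (> 0.5) / neutral
PHD-SNP   disease probability      disease (> 0.5) / neutral
========  =======================  ==========================================

PANTHER, SNPs&GO and PHD-SNP may also be reported as a disease probability
with a printed label; when a printed label and the re-thresholded
probability disagree the profile records a conflict instead of silently
resolving it.

Note on the SIFT boundary: a score of exactly 0.05 is categorized
*deleterious*, following the tool's own convention (<= 0.05) and the
published score tables, in which a 0.05 entry carries a "Deleterious"
label.  All other thresholds are strict, so every other boundary value
falls in the non-extreme class (DDG of exactly -0.5 is neutral, PROVEAN
-2.5 is neutral, PSIC 0.85 is possibly_damaging, subPSEC -3 is neutral,
probability 0.5 is neutral).

This module never invokes the external tools; it only interprets their
outputs.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .variants import MutationRecord, parse_mutation_name

__all__ = [
    "Tool",
    "ToolCall",
    "PredictorProfile",
    "NetSurfPRecord",
    "categorize",
    "is_damaging",
    "canonical_label",
    "read_score_table",
]


class Tool(str, enum.Enum):
    SIFT = "sift"
    POLYPHEN = "polyphen"
    IMUTANT = "imutant"
    PROVEAN = "provean"
    PANTHER = "panther"
    SNPSGO = "snpsgo"
    PHDSNP = "phdsnp"


#: calls that count as "damaging" for funnel / pathogenic-index purposes
_DAMAGING_VOCAB: Dict[Tool, Dict[str, bool]] = {
    Tool.SIFT: {"deleterious": True, "tolerated": False},
    Tool.POLYPHEN: {"probably_damaging": True, "possibly_damaging": False, "benign": False},
    Tool.IMUTANT: {"large_decrease": True, "large_increase": False, "neutral": False},
    Tool.PROVEAN: {"deleterious": True, "neutral": False},
    Tool.PANTHER: {"deleterious": True, "disease": True, "neutral": False},
    Tool.SNPSGO: {"disease": True, "neutral": False},
    Tool.PHDSNP: {"disease": True, "neutral": False},
}

_LABEL_ALIASES = {
    "deleterious": "deleterious",
    "tolerated": "tolerated",
    "probably damaging": "probably_damaging",
    "probably_damaging": "probably_damaging",
    "possibly damaging": "possibly_damaging",
    "possibly_damaging": "possibly_damaging",
    "benign": "benign",
    "large decrease": "large_decrease",
    "large_decrease": "large_decrease",
    "large increase": "large_increase",
    "large_increase": "large_increase",
    "neutral": "neutral",
    "disease": "disease",
}


def canonical_label(label: str) -> str:
    """Map a printed categorical label onto the canonical vocabulary."""
    key = label.strip().lower()
    try:
        return _LABEL_ALIASES[key]
    except KeyError:
        raise ValueError(f"unrecognized categorical label: {label!r}") from None


def categorize(tool: Union[Tool, str], score: float) -> str:
    """Categorize a numeric score on the given tool's primary scale.

    For PANTHER the primary scale is subPSEC; for SNPs&GO and PHD-SNP it is
    the disease probability.
    """
    tool = Tool(tool)
    if not isinstance(score, (int, float)) or isinstance(score, bool) or math.isnan(score):
        raise ValueError(f"non-numeric score for {tool.value}: {score!r}")
    if tool is Tool.SIFT:
        return "deleterious" if score <= 0.05 else "tolerated"
    if tool is Tool.POLYPHEN:
        if score > 0.85:
            return "probably_damaging"
        return "possibly_damaging" if score > 0.15 else "benign"
    if tool is Tool.IMUTANT:
        if score < -0.5:
            return "large_decrease"
        return "large_increase" if score > 0.5 else "neutral"
    if tool is Tool.PROVEAN:
        return "deleterious" if score < -2.5 else "neutral"
    if tool is Tool.PANTHER:
        return "deleterious" if score < -3 else "neutral"
    # SNPs&GO / PHD-SNP disease probability
    return "disease" if score > 0.5 else "neutral"


def categorize_probability(probability: float) -> str:
    """disease/neutral call from a disease probability (> 0.5 -> disease)."""
    if math.isnan(probability):
        raise ValueError("non-numeric probability")
    return "disease" if probability > 0.5 else "neutral"


def is_damaging(tool: Union[Tool, str], call: str) -> bool:
    """Map a tool's categorical call onto the binary used by funnel and PI."""
    tool = Tool(tool)
    vocab = _DAMAGING_VOCAB[tool]
    call = canonical_label(call)
    if call not in vocab:
        raise ValueError(f"{call!r} is not in the vocabulary of {tool.value}")
    return vocab[call]


@dataclass
class ToolCall:
    """One tool's output for one variant: numeric score and/or printed label.

    ``score`` is on the tool's primary scale; for the probability-reporting
    tools ``probability`` is an alias slot (PANTHER in consensus tables is
    reported as a probability rather than subPSEC).
    """

    tool: Tool
    score: Optional[float] = None
    probability: Optional[float] = None
    label: Optional[str] = None

    def derived_call(self) -> Optional[str]:
        """Categorical call re-derived from the numeric value, if any."""
        if self.score is not None:
            return categorize(self.tool, self.score)
        if self.probability is not None:
            return categorize_probability(self.probability)
        return None

    def call(self, mode: str = "labels") -> Optional[str]:
        """The operative categorical call.

        mode="labels": trust the printed label, fall back to the numeric
        value; mode="thresholds": re-derive from the numeric value, fall
        back to the label.
        """
        if mode not in ("labels", "thresholds"):
            raise ValueError(f"unknown mode {mode!r}")
        printed = canonical_label(self.label) if self.label is not None else None
        derived = self.derived_call()
        if mode == "labels":
            return printed if printed is not None else derived
        return derived if derived is not None else printed

    def conflict(self) -> bool:
        """True when printed label and re-derived call disagree on damaging."""
        printed = canonical_label(self.label) if self.label is not None else None
        derived = self.derived_call()
        if printed is None or derived is None:
            return False
        return is_damaging(self.tool, printed) != is_damaging(self.tool, derived)


@dataclass
class NetSurfPRecord:
    """Surface-accessibility record (stored as published, never recomputed)."""

    snp_id: str
    residue: str
    position: int
    state: str  # native | mutant
    rsa: float
    asa: float
    z_fit: float
    burial_class: str  # Buried | Exposed


@dataclass
class PredictorProfile:
    """All available tool outputs for one variant (0-7 slots filled)."""

    variant: MutationRecord
    calls: Dict[Tool, ToolCall] = field(default_factory=dict)
    surface: List[NetSurfPRecord] = field(default_factory=list)

    @property
    def snp_id(self) -> Optional[str]:
        return self.variant.dbsnp_id

    @property
    def identifier(self) -> str:
        return self.variant.dbsnp_id or self.variant.normalized_name

    @property
    def available_tools(self) -> int:
        return len(self.calls)

    def call(self, tool: Tool, mode: str = "labels") -> Optional[str]:
        tc = self.calls.get(tool)
        return tc.call(mode) if tc is not None else None

    def damaging(self, tool: Tool, mode: str = "labels") -> Optional[bool]:
        """True/False for a present slot, None for an absent one."""
        call = self.call(tool, mode)
        return None if call is None else is_damaging(tool, call)

    def damaging_count(self, mode: str = "labels") -> int:
        return sum(1 for t in self.calls if self.damaging(t, mode))

    def conflicts(self) -> List[Tool]:
        """Tools whose printed label disagrees with their numeric value."""
        return [t for t, tc in self.calls.items() if tc.conflict()]


# documented score-table dialect: numeric columns on each tool's primary
# scale, *_label columns carrying printed categorical labels
_NUMERIC_COLUMNS = {
    "sift": (Tool.SIFT, "score"),
    "polyphen": (Tool.POLYPHEN, "score"),
    "imutant_ddg": (Tool.IMUTANT, "score"),
    "provean": (Tool.PROVEAN, "score"),
    "panther_subpsec": (Tool.PANTHER, "score"),
    "panther_p": (Tool.PANTHER, "probability"),
    "snpsgo_p": (Tool.SNPSGO, "probability"),
    "phdsnp_p": (Tool.PHDSNP, "probability"),
}
_LABEL_COLUMNS = {
    "sift_label": Tool.SIFT,
    "polyphen_label": Tool.POLYPHEN,
    "imutant_label": Tool.IMUTANT,
    "provean_label": Tool.PROVEAN,
    "panther_label": Tool.PANTHER,
    "snpsgo_label": Tool.SNPSGO,
    "phdsnp_label": Tool.PHDSNP,
}


def read_score_table(
    path: Union[str, Path],
    fmt: Optional[str] = None,
) -> List[PredictorProfile]:
    """Read a per-variant score table (TSV or CSV) into profiles.

    The header must contain ``snp_id`` and/or ``mutation``; any subset of
    the documented numeric and ``*_label`` columns may be present.  Empty
    cells leave the corresponding tool slot absent.
    """
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = "," if fmt == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"snp_id": str, "mutation": str}, comment="#")
    cols = set(df.columns)
    if "snp_id" not in cols and "mutation" not in cols:
        raise ValueError(
            f"{path}: score table must contain an 'snp_id' or 'mutation' column; "
            f"found columns {sorted(cols)}"
        )
    unknown = cols - set(_NUMERIC_COLUMNS) - set(_LABEL_COLUMNS) - {
        "snp_id",
        "mutation",
        "mutation_printed",
        "true_label",
    }
    if unknown:
        raise ValueError(f"{path}: unrecognized columns {sorted(unknown)}")

    profiles: List[PredictorProfile] = []
    for i, row in df.iterrows():
        name = row.get("mutation")
        snp_id = row.get("snp_id")
        if (name is None or pd.isna(name)) and (snp_id is None or pd.isna(snp_id)):
            raise ValueError(f"{path}: row {i + 2} has neither snp_id nor mutation")
        if name is None or pd.isna(name):
            name = str(snp_id)
        variant = parse_mutation_name(str(name), dbsnp_id=None if pd.isna(snp_id) else str(snp_id))
        calls: Dict[Tool, ToolCall] = {}
        for col, (tool, slot) in _NUMERIC_COLUMNS.items():
            if col in cols and not pd.isna(row[col]):
                tc = calls.setdefault(tool, ToolCall(tool))
                setattr(tc, slot, float(row[col]))
        for col, tool in _LABEL_COLUMNS.items():
            if col in cols and not pd.isna(row[col]):
                tc = calls.setdefault(tool, ToolCall(tool))
                tc.label = str(row[col])
        profiles.append(PredictorProfile(variant=variant, calls=calls))
    return profiles


def merge_profiles(*profile_lists: Sequence[PredictorProfile]) -> List[PredictorProfile]:
    """Merge profile lists on the variant identifier (dbSNP id when present).

    Later lists fill tool slots missing from earlier ones; slot collisions
    merge field-wise (numeric from one source, label from another).  The
    merge key pairs the dbSNP id with the protein change, because one rs id
    can name two substitutions (e.g. an rs with both a P533A and a P533S
    allele).
    """
    merged: Dict[tuple, PredictorProfile] = {}
    order: List[tuple] = []
    for plist in profile_lists:
        for p in plist:
            key = (p.variant.dbsnp_id, p.variant.normalized_name)
            if key not in merged:
                merged[key] = PredictorProfile(variant=p.variant, calls=dict(p.calls))
                order.append(key)
            else:
                target = merged[key]
                for tool, tc in p.calls.items():
                    if tool not in target.calls:
                        target.calls[tool] = tc
                    else:
                        existing = target.calls[tool]
                        if existing.score is None:
                            existing.score = tc.score
                        if existing.probability is None:
                            existing.probability = tc.probability
                        if existing.label is None:
                            existing.label = tc.label
    return [merged[k] for k in order]
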