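"""Curated IDUA mutation-severity knowledge base and diallelic phenotype rules.

MPS I is autosomal recessive, so the clinical phenotype is a function of the
severity of *both* alleles.  The knowledge base maps each curated mutation to
a severity set over {mild, intermediate, severe} (multi-valued where the
case reports disagree) or {unknown}; entries whose literature support is
thin carry a low-reliability flag.

Two per-allele severities combine into a phenotype by four rules:

1. severe x severe                -> Hurler
2. mild x severe                  -> Scheie;  intermediate x severe -> Hurler-Scheie
3. intermediate x intermediate    -> Hurler-Scheie or Scheie (ambiguous)
4. any allele mild                -> Scheie (overrides rule 3 for mild x
   intermediate; consistent with rule 2's mild branch)

Any allele of unknown severity makes the phenotype unknown.  Set-valued
severities propagate by Cartesian closure: the phenotype set is the union of
the atomic results over every pair drawn from the two severity sets —
collapsing multi-valued predictions to a single "worst case" would fabricate
certainty the curation does not have.

Computational evidence (including the ensemble score used for novel
variants) counts as supporting-level only; phenotype calls here are
literature-derived predictions, not diagnoses.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, List, Optional, Tuple

import pandas as pd

from .predictors import PredictorProfile
from .scoring import classify, compute_pi
from .variants import MutationRecord, MutationClass, normalize_name, parse_mutation_name

__all__ = [
    "Severity",
    "Phenotype",
    "SeverityAssignment",
    "PhenotypeCall",
    "load_kb",
    "combine_atomic",
    "combine_alleles",
    "predict_phenotype",
    "kb_category_counts",
]


class Severity(str, enum.Enum):
    MILD = "mild"
    INTERMEDIATE = "intermediate"
    SEVERE = "severe"
    UNKNOWN = "unknown"


class Phenotype(str, enum.Enum):
    HURLER = "Hurler"
    HURLER_SCHEIE = "Hurler-Scheie"
    SCHEIE = "Scheie"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class SeverityAssignment:
    """A curated mutation with its severity set and reliability flag."""

    mutation: MutationRecord
    severities: FrozenSet[Severity]
    low_reliability: bool = False
    source: Optional[str] = None

    def __post_init__(self):
        if not self.severities:
            raise ValueError("severity set must be non-empty")
        if Severity.UNKNOWN in self.severities and len(self.severities) > 1:
            raise ValueError("unknown cannot co-occur with another severity")


@dataclass
class PhenotypeCall:
    """Set-valued phenotype prediction with a per-allele provenance trace."""

    phenotypes: FrozenSet[Phenotype]
    trace: List[dict] = field(default_factory=list)
    note: str = (
        "computational evidence is supporting-level only; confirm "
        "biochemically and clinically"
    )

    def to_dict(self) -> dict:
        return {
            "phenotypes": sorted(p.value for p in self.phenotypes),
            "trace": self.trace,
            "note": self.note,
        }


def combine_atomic(a: Severity, b: Severity) -> FrozenSet[Phenotype]:
    """Phenotype set for a single pair of atomic allele severities."""
    pair = {a, b}
    if Severity.UNKNOWN in pair:
        return frozenset({Phenotype.UNKNOWN})
    if Severity.MILD in pair:  # rule 4 (subsumes rule 2's mild branch)
        return frozenset({Phenotype.SCHEIE})
    if pair == {Severity.SEVERE}:  # rule 1
        return frozenset({Phenotype.HURLER})
    if pair == {Severity.INTERMEDIATE, Severity.SEVERE}:  # rule 2
        return frozenset({Phenotype.HURLER_SCHEIE})
    # rule 3: intermediate x intermediate
    return frozenset({Phenotype.HURLER_SCHEIE, Phenotype.SCHEIE})


def combine_alleles(
    a: FrozenSet[Severity], b: FrozenSet[Severity]
) -> PhenotypeCall:
    """Cartesian closure of :func:`combine_atomic` over two severity sets."""
    if not a or not b:
        raise ValueError("allele severity sets must be non-empty")
    phenotypes: set = set()
    fired: List[dict] = []
    for sa in sorted(a, key=lambda s: s.value):
        for sb in sorted(b, key=lambda s: s.value):
            result = combine_atomic(sa, sb)
            phenotypes |= result
            fired.append(
                {
                    "pair": sorted([sa.value, sb.value]),
                    "phenotypes": sorted(p.value for p in result),
                }
            )
    return PhenotypeCall(phenotypes=frozenset(phenotypes), trace=fired)


_KB_FILES = ("severity_missense_nonsense.tsv", "severity_splice_indel.tsv")


def _parse_severities(cell: str) -> FrozenSet[Severity]:
    return frozenset(Severity(tok.strip()) for tok in str(cell).split(","))


def load_kb() -> Dict[str, SeverityAssignment]:
    """Load the packaged severity tables into a name-keyed knowledge base.

    Severity sets are multi-valued where the curation is ("mild,
    intermediate"); "unknown" is a singleton; footnoted entries carry
    low_reliability=True.  The class column follows the tables' category
    placement (stop-loss and start-loss substitutions sit with missense;
    3308del12 and c.1-2C>G with splicing; D444/445 with
    deletions/insertions).  Duplicate normalized names raise.
    """
    kb: Dict[str, SeverityAssignment] = {}
    collisions: List[str] = []
    for fname in _KB_FILES:
        with resources.files("saamp.data").joinpath(fname).open() as fh:
            df = pd.read_csv(fh, sep="\t")
        for _, row in df.iterrows():
            name = str(row["mutation"])
            parsed = parse_mutation_name(str(row["mutation_printed"]))
            # category placement in the source tables wins over the
            # pattern-derived class (e.g. D444/445, c.1-2C>G)
            record = MutationRecord(
                raw_name=parsed.raw_name,
                normalized_name=parsed.normalized_name,
                mutation_class=MutationClass(row["class"]),
                protein_position=parsed.protein_position,
                ref_residue=parsed.ref_residue,
                alt_residue=parsed.alt_residue,
            )
            if name in kb:
                collisions.append(name)
                continue
            kb[name] = SeverityAssignment(
                mutation=record,
                severities=_parse_severities(row["severities"]),
                low_reliability=bool(row["low_reliability"]),
                source=str(row["source"]),
            )
    if collisions:
        raise ValueError(f"duplicate knowledge-base names: {collisions}")
    return kb


def kb_lookup(
    kb: Dict[str, SeverityAssignment], name: str
) -> Optional[SeverityAssignment]:
    """Case-sensitive lookup of a normalized name, with a case-insensitive
    fallback that warns."""
    key = normalize_name(name)
    if key in kb:
        return kb[key]
    lowered = {k.lower(): k for k in kb}
    if key.lower() in lowered:
        warnings.warn(
            f"knowledge-base match for {name!r} required case folding "
            f"({lowered[key.lower()]!r})",
            stacklevel=2,
        )
        return kb[lowered[key.lower()]]
    return None


def kb_category_counts(kb: Dict[str, SeverityAssignment]) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for entry in kb.values():
        c = entry.mutation.mutation_class.value
        counts[c] = counts.get(c, 0) + 1
    counts["total"] = len(kb)
    return counts


def predict_phenotype(
    allele1: str,
    allele2: str,
    profiles: Optional[Dict[str, PredictorProfile]] = None,
    kb: Optional[Dict[str, SeverityAssignment]] = None,
    cutoff: str = "sensitive",
) -> PhenotypeCall:
    """Diallelic phenotype prediction with a per-allele workflow trace.

    Per allele: a knowledge-base hit supplies its curated severity set;
    otherwise, if an ensemble score profile is supplied for that allele,
    the variant is classified pathogenic/benign (recorded in the trace —
    the ensemble cannot grade severity, so severity stays unknown);
    otherwise severity is unknown.
    """
    if kb is None:
        kb = load_kb()
    severity_sets: List[FrozenSet[Severity]] = []
    allele_trace: List[dict] = []
    for i, name in enumerate((allele1, allele2), start=1):
        record = parse_mutation_name(name)  # raises on empty name
        entry = kb_lookup(kb, record.normalized_name)
        if entry is not None:
            severity_sets.append(entry.severities)
            allele_trace.append(
                {
                    "allele": i,
                    "name": record.normalized_name,
                    "path": "knowledge_base",
                    "severities": sorted(s.value for s in entry.severities),
                    "low_reliability": entry.low_reliability,
                }
            )
            continue
        profile = (profiles or {}).get(record.normalized_name)
        if profile is not None and profile.available_tools > 0:
            call = classify(compute_pi(profile), cutoff)
            severity_sets.append(frozenset({Severity.UNKNOWN}))
            allele_trace.append(
                {
                    "allele": i,
                    "name": record.normalized_name,
                    "path": "ensemble_score",
                    "classification": call,
                    "severities": ["unknown"],
                }
            )
        else:
            severity_sets.append(frozenset({Severity.UNKNOWN}))
            allele_trace.append(
                {
                    "allele": i,
                    "name": record.normalized_name,
                    "path": "not in knowledge base, no scores",
                    "severities": ["unknown"],
                }
            )
    call = combine_alleles(severity_sets[0], severity_sets[1])
    call.trace = allele_trace + [{"rules": call.trace}]
    return call
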