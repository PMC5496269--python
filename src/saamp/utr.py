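"""Functional flagging of untranslated-region variants.

Two annotation routes, both operating on records supplied to the module
(it does not scan sequences for motifs):

* UTR regulatory elements: a variant is functionally significant when the
  set of recognized cis-elements differs between the reference and variant
  alleles (e.g. loss of an IRES, gain of a 15-LOX-DICE).  "No pattern" is a
  first-class state, represented as ``None``.
* miRNA target sites (3' UTR): polymorphic sites fall into four classes —
  D disrupts a conserved site, N disrupts a non-conserved site, C creates a
  new site, O leaves the ancestral allele undetermined.  D and C are the
  classes with likely functional impact (loss of normal repression and
  gain of abnormal repression, respectively).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Union

import pandas as pd

__all__ = [
    "UtrPatternRecord",
    "MirnaSiteRecord",
    "flag_utr_pattern_change",
    "flag_mirna_site",
    "read_utr_patterns",
    "read_mirna_sites",
]

_NO_PATTERN_TOKENS = {"no pattern", "no_pattern", "none", ""}


def _element(cell) -> Optional[str]:
    """Map the table's 'no pattern' token (or an empty cell) to None."""
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return None
    text = str(cell).strip()
    return None if text.lower() in _NO_PATTERN_TOKENS else text


@dataclass(frozen=True)
class UtrPatternRecord:
    snp_id: str
    nucleotide_change: str
    utr_side: str  # 5prime | 3prime
    element_before: Optional[str]
    element_after: Optional[str]


@dataclass(frozen=True)
class MirnaSiteRecord:
    snp_id: str
    mirna_id: str
    conservation: int
    mir_site: str  # seed-complement bases capitalized
    function_class: str  # D | N | C | O


def flag_utr_pattern_change(rec: UtrPatternRecord) -> bool:
    """True iff the functional element differs between alleles."""
    return rec.element_before != rec.element_after


def flag_mirna_site(rec: MirnaSiteRecord) -> str:
    """'likely_functional' for classes C and D; 'not_flagged' for N and O."""
    cls = rec.function_class.strip().upper()
    if cls not in {"D", "N", "C", "O"}:
        raise ValueError(f"unknown miRNA-site class {rec.function_class!r}")
    return "likely_functional" if cls in {"C", "D"} else "not_flagged"


def read_utr_patterns(path: Union[str, Path]) -> List[UtrPatternRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        UtrPatternRecord(
            snp_id=row["snp_id"],
            nucleotide_change=row["nucleotide_change"],
            utr_side=row["utr_side"],
            element_before=_element(row["element_before"]),
            element_after=_element(row["element_after"]),
        )
        for _, row in df.iterrows()
    ]


def read_mirna_sites(path: Union[str, Path]) -> List[MirnaSiteRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        MirnaSiteRecord(
            snp_id=row["snp_id"],
            mirna_id=row["mirna_id"],
            conservation=int(row["conservation"]),
            mir_site=row["mir_site"],
            function_class=row["function_class"],
        )
        for _, row in df.iterrows()
    ]
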