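"""Parsing of legacy IDUA mutation nomenclature.

The MPS I literature predates systematic HGVS usage; mutations are quoted in
"old-style" names: protein substitutions (``P533R``, ``W402X``), intron
("intervening sequence") splice notation (``IVS5-7G>A``), and bare
coding-coordinate indels (``1995del11``, ``c.1593delG``, ``396insAC``).
This module normalizes such names and assigns each to one of four broad
mutation classes. It is deliberately forgiving: anything unrecognized is
preserved verbatim with class ``unknown`` rather than rejected, because
downstream lookups against the curated severity tables should never be
blocked by an exotic name.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, asdict
from typing import Iterable, Optional

__all__ = [
    "MutationClass",
    "MutationRecord",
    "normalize_name",
    "parse_mutation_name",
    "records_to_tsv",
    "records_to_json",
]


class MutationClass(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SPLICING = "splicing"
    DELETION_INSERTION = "deletion_insertion"
    UNKNOWN = "unknown"


# Protein-level substitution, e.g. P533R, W402X, X654C (stop-loss), M1T.
# One-letter ref, 1-based position, one-letter alt; "X" denotes a stop.
_SUBSTITUTION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")

# del/ins/dup tokens are lowercase in the legacy names (e.g. 1995del11,
# 396insAC, c.1147dupG, c.956_972+9delinsTA, 702ins10del22).
_INDEL_TOKEN_RE = re.compile(r"(delins|del|ins|dup)")


def normalize_name(raw: str) -> str:
    """Strip all internal whitespace from a printed mutation name.

    Journal table rendering introduces spurious spaces ("F247 L",
    "IVS5-7G > A"); they are typography, not semantics.  Non-breaking
    spaces and en-dashes are normalized along the way.
    """
    s = raw.replace("–", "-").replace("−", "-")
    return re.sub(r"\s+", "", s, flags=re.UNICODE)


@dataclass(frozen=True)
class MutationRecord:
    """A parsed legacy-nomenclature mutation.

    ``protein_position``, ``ref_residue`` and ``alt_residue`` are populated
    only for protein-level substitutions (missense/nonsense); ``alt_residue``
    is ``"*"`` for nonsense.  ``dbsnp_id`` is carried when known.
    """

    raw_name: str
    normalized_name: str
    mutation_class: MutationClass
    protein_position: Optional[int] = None
    ref_residue: Optional[str] = None
    alt_residue: Optional[str] = None
    dbsnp_id: Optional[str] = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mutation_class"] = self.mutation_class.value
        return d


def parse_mutation_name(raw: str, dbsnp_id: Optional[str] = None) -> MutationRecord:
    """Parse a legacy mutation name into a :class:`MutationRecord`.

    Classification rules, in order:

    * ``<AA><pos>X``             -> nonsense (stop gain)
    * ``<AA><pos><AA>``          -> missense (includes stop-loss ``X654C``
                                    and start-loss ``M1T`` style names,
                                    which the severity tables group with
                                    missense)
    * names beginning ``IVS``    -> splicing
    * names containing ``del``/``ins``/``dup``/``delins`` -> deletion_insertion
    * anything else              -> unknown (never an error)
    """
    if not raw or not raw.strip():
        raise ValueError("mutation name must be non-empty")
    name = normalize_name(raw)

    m = _SUBSTITUTION_RE.match(name)
    if m:
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if alt == "X":
            return MutationRecord(raw, name, MutationClass.NONSENSE, pos, ref, "*", dbsnp_id)
        return MutationRecord(raw, name, MutationClass.MISSENSE, pos, ref, alt, dbsnp_id)

    if name.startswith("IVS"):
        return MutationRecord(raw, name, MutationClass.SPLICING, dbsnp_id=dbsnp_id)

    if _INDEL_TOKEN_RE.search(name):
        return MutationRecord(raw, name, MutationClass.DELETION_INSERTION, dbsnp_id=dbsnp_id)

    return MutationRecord(raw, name, MutationClass.UNKNOWN, dbsnp_id=dbsnp_id)


_TSV_COLUMNS = ("raw_name", "normalized_name", "class", "position", "ref", "alt")


def records_to_tsv(records: Iterable[MutationRecord]) -> str:
    """Serialize records as TSV (columns raw_name/normalized_name/class/position/ref/alt)."""
    lines = ["\t".join(_TSV_COLUMNS)]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.raw_name,
                    r.normalized_name,
                    r.mutation_class.value,
                    "" if r.protein_position is None else str(r.protein_position),
                    r.ref_residue or "",
                    r.alt_residue or "",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def records_to_json(records: Iterable[MutationRecord]) -> str:
    return json.dumps([r.to_dict() for r in records], indent=2)
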