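"""Sequential screening funnel over the ensemble predictors.

The published screen runs missense variants through the tools in sequence —
SIFT, then PolyPhen, then I-Mutant, then PROVEAN — keeping only variants
called damaging at each stage, and finally requires a three-way consensus
(PANTHER and SNPs&GO and PHD-SNP all "disease").  Because every stage is an
independent per-variant predicate, the final survivor set does not depend on
the order of the first four stages; the funnel exists to report the
per-stage attrition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .predictors import PredictorProfile, Tool, is_damaging

__all__ = ["FunnelReport", "StageResult", "run_funnel", "STAGES"]

#: stage name -> tools that must all be damaging for a profile to survive
STAGES: Dict[str, tuple] = {
    "sift": (Tool.SIFT,),
    "polyphen": (Tool.POLYPHEN,),
    "imutant": (Tool.IMUTANT,),
    "provean": (Tool.PROVEAN,),
    "consensus": (Tool.PANTHER, Tool.SNPSGO, Tool.PHDSNP),
}


@dataclass
class StageResult:
    name: str
    entering: int
    surviving: int
    survivor_ids: List[str]
    not_evaluated: List[str] = field(default_factory=list)  # missing-slot eliminations


@dataclass
class FunnelReport:
    stages: List[StageResult]
    mode: str
    #: the surviving profiles themselves (ids can collide when one dbSNP id
    #: names two substitutions, so downstream code should prefer these)
    survivors: List[PredictorProfile] = field(default_factory=list)

    @property
    def stage_names(self) -> List[str]:
        return [s.name for s in self.stages]

    @property
    def final_survivors(self) -> List[str]:
        return self.stages[-1].survivor_ids if self.stages else []

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "mode": self.mode,
            "stages": [
                {
                    "name": s.name,
                    "entering": s.entering,
                    "surviving": s.surviving,
                    "survivor_ids": s.survivor_ids,
                    "not_evaluated": s.not_evaluated,
                }
                for s in self.stages
            ],
        }

    def to_tsv(self) -> str:
        lines = ["stage\tentering\tsurviving\tnot_evaluated"]
        for s in self.stages:
            lines.append(f"{s.name}\t{s.entering}\t{s.surviving}\t{len(s.not_evaluated)}")
        return "\n".join(lines) + "\n"


def run_funnel(
    profiles: Sequence[PredictorProfile],
    mode: str = "labels",
    strict: bool = False,
    stage_order: Optional[Sequence[str]] = None,
) -> FunnelReport:
    """Run the five-stage screen and report per-stage survivors.

    mode="labels" trusts printed categorical labels where available;
    mode="thresholds" re-derives calls from numeric scores.  A profile
    missing a stage's tool slot is eliminated at that stage with a
    "not evaluated" mark (distinct from "not damaging") — or, under
    ``strict=True``, raises a ValueError naming the variant and stage.
    Deterministic and order-preserving.  ``stage_order`` reorders or
    subsets the stages (each stage is an independent predicate, so
    permuting them cannot change the final survivor set).
    """
    if stage_order is None:
        stage_order = list(STAGES)
    unknown = [s for s in stage_order if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown funnel stages: {unknown}")
    current = list(profiles)
    stage_results: List[StageResult] = []
    for stage_name in stage_order:
        tools = STAGES[stage_name]
        survivors: List[PredictorProfile] = []
        not_evaluated: List[str] = []
        for p in current:
            flags = []
            missing = False
            for tool in tools:
                call = p.call(tool, mode)
                if call is None:
                    missing = True
                    break
                flags.append(is_damaging(tool, call))
            if missing:
                if strict:
                    raise ValueError(
                        f"variant {p.identifier} has no {stage_name} prediction "
                        f"(strict mode)"
                    )
                not_evaluated.append(p.identifier)
                continue
            if all(flags):
                survivors.append(p)
        stage_results.append(
            StageResult(
                name=stage_name,
                entering=len(current),
                surviving=len(survivors),
                survivor_ids=[p.identifier for p in survivors],
                not_evaluated=not_evaluated,
            )
        )
        current = survivors
    return FunnelReport(stages=stage_results, mode=mode, survivors=current)
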