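"""Synthetic labelled benchmarks for exercising the ensemble classifier.

The generator emulates the *structure* of a curated benchmark — a set of
variants of known pathogenic/benign status, each scored by up to seven
binary classifiers — without simulating the tools' numeric score
distributions (binary calls are all the ensemble index consumes).  Defaults
mirror a plausible curated panel: per-tool sensitivity and specificity of
0.85, no missingness, independent tools.  An optional correlation knob
(shared latent per-variant "difficulty" pushed through a logistic link) is
provided because real predictors trained on overlapping data correlate; it
is an extension beyond the published design and defaults to off.

Mutation names are synthesized in the legacy nomenclature styles
(substitutions, stop gains, IVS splice names, bare-coordinate indels) so
the same benchmarks double as parser fuzz input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .predictors import PredictorProfile, Tool, ToolCall
from .variants import parse_mutation_name

__all__ = ["GeneratorConfig", "generate_benchmark", "benchmark_to_tsv"]

#: the binary vocabulary each tool's synthetic call uses
_CALL_WORDS: Dict[Tool, Tuple[str, str]] = {
    Tool.SIFT: ("deleterious", "tolerated"),
    Tool.POLYPHEN: ("probably_damaging", "benign"),
    Tool.IMUTANT: ("large_decrease", "neutral"),
    Tool.PROVEAN: ("deleterious", "neutral"),
    Tool.PANTHER: ("deleterious", "neutral"),
    Tool.SNPSGO: ("disease", "neutral"),
    Tool.PHDSNP: ("disease", "neutral"),
}

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic benchmark.

    ``tool_sensitivity``/``tool_specificity`` may be a single float applied
    to all seven tools or a per-tool mapping.  ``missingness`` is the
    per-tool probability that a slot is absent.  ``correlation`` in [0, 1)
    scales the shared latent difficulty (0 = independent tools).
    """

    n_pathogenic: int
    n_benign: int
    tool_sensitivity: Union[float, Dict[Tool, float]] = 0.85
    tool_specificity: Union[float, Dict[Tool, float]] = 0.85
    missingness: float = 0.0
    correlation: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pathogenic < 0 or self.n_benign < 0:
            raise ValueError("sample sizes must be non-negative")
        for p in (*self._per_tool(self.tool_sensitivity).values(),
                  *self._per_tool(self.tool_specificity).values(),
                  self.missingness):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must lie in [0, 1)")

    @staticmethod
    def _per_tool(value: Union[float, Dict[Tool, float]]) -> Dict[Tool, float]:
        if isinstance(value, dict):
            return {Tool(t): float(p) for t, p in value.items()}
        return {t: float(value) for t in Tool}

    @property
    def sensitivity_by_tool(self) -> Dict[Tool, float]:
        return self._per_tool(self.tool_sensitivity)

    @property
    def specificity_by_tool(self) -> Dict[Tool, float]:
        return self._per_tool(self.tool_specificity)


def _synth_name(rng: np.random.Generator) -> str:
    style = rng.integers(0, 4)
    pos = int(rng.integers(1, 700))
    if style == 0:  # missense
        ref, alt = rng.choice(list(_AA), size=2)
        return f"{ref}{pos}{alt}"
    if style == 1:  # stop gain
        ref = rng.choice(list(_AA))
        return f"{ref}{pos}X"
    if style == 2:  # splice
        intron = int(rng.integers(1, 13))
        offset = int(rng.integers(1, 8))
        sign = "+" if rng.random() < 0.5 else "-"
        a, b = rng.choice(list("ACGT"), size=2)
        return f"IVS{intron}{sign}{offset}{a}>{b}"
    op = "del" if rng.random() < 0.5 else "ins"
    length = int(rng.integers(1, 12))
    return f"{pos}{op}{length}"


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_benchmark(
    cfg: GeneratorConfig,
) -> Tuple[List[PredictorProfile], List[str]]:
    """Draw a labelled benchmark: profiles with binary calls + true labels.

    Each tool's call is an independent Bernoulli draw given the true label
    — damaging with probability tool_sensitivity for pathogenic variants
    and 1 - tool_specificity for benign ones.  With ``correlation`` > 0, a
    per-variant latent difficulty z ~ N(0, 1) shifts every tool's logit by
    c/(1-c) * z, inducing positive inter-tool correlation while keeping the
    marginal rates approximately calibrated.  Label balance is exact;
    output is reproducible given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    sens = cfg.sensitivity_by_tool
    spec = cfg.specificity_by_tool

    labels = ["pathogenic"] * cfg.n_pathogenic + ["benign"] * cfg.n_benign
    profiles: List[PredictorProfile] = []
    seen: set = set()
    for label in labels:
        name = _synth_name(rng)
        while name in seen:
            name = _synth_name(rng)
        seen.add(name)
        z = rng.standard_normal() if cfg.correlation > 0 else 0.0
        shift = cfg.correlation / (1.0 - cfg.correlation)
        calls: Dict[Tool, ToolCall] = {}
        for tool in Tool:
            if cfg.missingness > 0 and rng.random() < cfg.missingness:
                continue
            p_damaging = sens[tool] if label == "pathogenic" else 1.0 - spec[tool]
            if cfg.correlation > 0:
                # shift the Bernoulli rate on the logit scale by the shared
                # latent difficulty; clip to keep logits finite
                p = float(np.clip(p_damaging, 1e-9, 1 - 1e-9))
                p_damaging = float(_logistic(np.log(p / (1 - p)) + shift * z))
            damaging = rng.random() < p_damaging
            word = _CALL_WORDS[tool][0 if damaging else 1]
            calls[tool] = ToolCall(tool, label=word)
        profiles.append(
            PredictorProfile(variant=parse_mutation_name(name), calls=calls)
        )
    return profiles, labels


def benchmark_to_tsv(
    profiles: Sequence[PredictorProfile],
    labels: Optional[Sequence[str]] = None,
) -> str:
    """Serialize a benchmark in the documented score-table dialect."""
    header = ["mutation"] + [f"{t.value}_label" for t in Tool]
    if labels is not None:
        header.append("true_label")
    lines = ["\t".join(header)]
    for i, p in enumerate(profiles):
        row = [p.variant.normalized_name]
        for t in Tool:
            tc = p.calls.get(t)
            row.append("" if tc is None or tc.label is None else tc.label)
        if labels is not None:
            row.append(labels[i])
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
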