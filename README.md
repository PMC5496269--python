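# saamp

Ensemble variant-effect scoring and genotype→phenotype prediction for
mucopolysaccharidosis type I (MPS I).

MPS I is an autosomal recessive lysosomal disease caused by deficiency of
α-L-iduronidase (IDUA). Its clinical spectrum — Hurler (severe),
Hurler-Scheie (intermediate), Scheie (mild) — matters for treatment
allocation, but genotype/phenotype correlation is hard to establish from
single predictors. `saamp` implements an in silico interpretation workflow
for IDUA variants, aimed at clinical geneticists and variant curators:

* **Legacy nomenclature parsing** — the MPS I literature quotes mutations as
  old-style names (`P533R`, `W402X`, `IVS5-7G>A`, `1995del11`); the parser
  normalizes them and assigns missense / nonsense / splicing /
  deletion-insertion classes.
* **SAAMP pathogenic index (PI)** — given categorical calls from up to seven
  predictors (SIFT, PolyPhen, I-Mutant, PROVEAN, PANTHER, SNPs&GO, PHD-SNP),

  PI = (# damaging calls) / (# tools with a prediction),

  classified *pathogenic* when the damaging count reaches
  k = ⌈c · n_available⌉, with c = 3/7 (sensitive mode, displayed 0.43) or
  c = 4/7 (specific mode, displayed 0.57). The cutoffs are implemented as
  exact count rules, never as comparisons against the rounded decimals.
* **Sequential screening funnel** — SIFT → PolyPhen → I-Mutant → PROVEAN →
  three-tool disease consensus, with per-stage survivor bookkeeping and a
  label-vs-threshold mode for handling printed-label/probability conflicts.
* **Severity knowledge base + diallelic rules** — a curated table of IDUA
  mutations with literature-derived severity sets, combined across the two
  alleles: severe×severe → Hurler; intermediate×severe → Hurler-Scheie;
  intermediate×intermediate → {Hurler-Scheie, Scheie}; any mild allele →
  Scheie; any unknown → unknown. Multi-valued severities propagate by
  Cartesian closure.
* **UTR flagging** — regulatory-element changes (IRES loss, 15-LOX-DICE
  gain) and polymorphic miRNA target-site classes (C/D flagged, N/O not).
* **Synthetic benchmarks** — a seeded generator of labelled tool-call
  profiles for calibrating and testing the ensemble.

The published score tables, UTR annotations and severity tables ship with
the package as TSV, so everything runs offline. This package interprets
predictor outputs; it never invokes the external web tools.

## Worked example

```python
from saamp import load_kb, load_table, predict_phenotype, run_funnel
from saamp.predictors import merge_profiles

merged = merge_profiles(load_table("damaging_screen").records,
                        load_table("disease_consensus").records)
report = run_funnel(merged, mode="labels")
print(" -> ".join(f"{s.name}:{s.surviving}" for s in report.stages))

kb = load_kb()
for genotype in [("W402X", "W402X"), ("W402X", "IVS5-7G>A"), ("R89Q", "W402X")]:
    call = predict_phenotype(*genotype, kb=kb)
    print(genotype, "->", sorted(p.value for p in call.phenotypes))
```

prints

```
sift:93 -> polyphen:93 -> imutant:93 -> provean:93 -> consensus:28
('W402X', 'W402X') -> ['Hurler']
('W402X', 'IVS5-7G>A') -> ['Scheie']
('R89Q', 'W402X') -> ['Hurler-Scheie', 'Scheie']
```

The funnel line shows the 93 variants already called damaging by the first
four tools passing those stages on their printed labels, with 28 surviving
the three-tool disease consensus. Two severe alleles predict Hurler; a
severe allele with the one mild splicing mutation predicts Scheie; an
allele whose curated severity is ambiguous ({mild, intermediate}) yields a
phenotype *set* rather than a forced single call.

More narrative walk-throughs live in `examples/` (scoring, funnel,
phenotype prediction, UTR annotation, benchmark calibration), and a thin
CLI exposes the same operations:

```bash
saamp score --scores scores.tsv --cutoff 0.43
saamp predict-phenotype --allele1 W402X --allele2 Q70X
saamp make-benchmark --n-path 81 --n-benign 15 --seed 1 -o bench.tsv
saamp kb-validate
```

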