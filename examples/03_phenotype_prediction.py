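"""Diallelic genotype -> phenotype prediction from the curated severity KB.

MPS I is recessive: the phenotype follows from the severity of both
alleles.  Severe x severe gives Hurler; any mild allele gives Scheie;
intermediate x severe gives Hurler-Scheie; multi-valued curated severities
propagate as phenotype sets rather than being collapsed.
"""

from saamp import load_kb, predict_phenotype

kb = load_kb()
genotypes = [
    ("W402X", "W402X"),       # two severe nonsense alleles
    ("W402X", "Q70X"),        # the two most common nonsense mutations
    ("W402X", "IVS5-7G>A"),   # severe x the one mild splicing mutation
    ("R89Q", "W402X"),        # {mild, intermediate} x severe
    ("W402X", "NOVEL999Z"),   # second allele unknown to the KB
]
for a, b in genotypes:
    call = predict_phenotype(a, b, kb=kb)
    phenotypes = "/".join(sorted(p.value for p in call.phenotypes))
    print(f"{a:>10} + {b:<12} -> {phenotypes}")
print("\nSet-valued outputs reflect genuine curation ambiguity; any unknown "
      "allele makes the phenotype unknown. Computational evidence is "
      "supporting-level only.")
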