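"""Flag UTR variants for likely functional impact.

5' UTR variants flag when the recognized regulatory element changes between
alleles (IRES loss, 15-LOX-DICE gain); 3' UTR variants flag when a
polymorphic miRNA target site is created (class C) or a conserved one
disrupted (class D).
"""

from saamp import flag_mirna_site, flag_utr_pattern_change, load_table

print("5' UTR regulatory-element changes:")
for r in load_table("utr_patterns").records:
    change = f"{r.element_before or 'no pattern'} -> {r.element_after or 'no pattern'}"
    print(f"  {r.snp_id:<12} {change:<28} functional={flag_utr_pattern_change(r)}")

print("\n3' UTR miRNA target sites (rs733349):")
for r in load_table("mirna_sites").records:
    print(f"  {r.mirna_id:<18} class {r.function_class}  {flag_mirna_site(r)}")
print("\nClass C sites are newly created (possible abnormal repression); "
      "class N disruptions are non-conserved and not flagged.")
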