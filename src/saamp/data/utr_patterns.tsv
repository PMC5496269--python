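snp_id	nucleotide_change	utr_side	element_before	element_after
rs577729544	G/A	5prime	IRES	no pattern
rs200237798	G/A	5prime	IRES	no pattern
rs372934646	C/A	5prime	IRES	no pattern
rs530362790	G/A	5prime	no pattern	15-LOX-DICE
rs765255638	G/T	5prime	IRES	no pattern
rs775542391	T/G	5prime	IRES	no pattern
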