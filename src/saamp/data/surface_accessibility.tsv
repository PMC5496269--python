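snp_id	residue	position	state	rsa	asa	z_fit	burial_class
rs121965021	P	533	native	0.341	48.43	-1.149	Buried
rs121965021	R	533	mutant	0.344	78.73	-0.651	Buried
rs371397270	D	349	native	0.241	34.699	-0.488	Buried
rs371397270	G	349	mutant	0.392	30.819	-1.405	Exposed
rs775816150	T	374	native	0.095	13.149	-1.852	Buried
rs775816150	P	374	mutant	0.233	33.134	-1.134	Buried
rs772416503	P	496	native	0.105	14.928	0.247	Buried
rs772416503	R	496	mutant	0.164	37.533	-0.253	Buried
rs121965033	L	346	native	0.031	5.603	0.342	Buried
rs121965033	R	346	mutant	0.108	24.09	-0.954	Buried
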