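snp_id	mirna_id	conservation	mir_site	function_class
rs733349	hsa-miR-128-3p	1	ggctgCACTGTGc	N
rs733349	hsa-miR-148a-3p	1	ggcTGCACTGtgc	N
rs733349	hsa-miR-148b-3p	1	ggcTGCACTGtgc	N
rs733349	hsa-miR-152-3p	1	ggcTGCACTGtgc	N
rs733349	hsa-miR-216a-3p	1	ggctgCACTGTGc	N
rs733349	hsa-miR-3681-3p	1	ggctgCACTGTGc	N
rs733349	hsa-miR-3944-5p	1	gGCTGCACtgtgc	N
rs733349	hsa-miR-7156-3p	1	GGCTGCActgtgc	N
rs733349	hsa-miR-4436b-3p	1	ggCTGCCCTgtgc	C
rs733349	hsa-miR-4632-5p	1	ggCTGCCCTgtgc	C
rs733349	hsa-miR-6735-5p	1	ggCTGCCCTgtgc	C
rs733349	hsa-miR-6879-5p	1	ggCTGCCCTgtgc	C
rs733349	hsa-miR-7843-5p	1	ggCTGCCCTgtgc	C
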