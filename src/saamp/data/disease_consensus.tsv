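snp_id	mutation	mutation_printed	phdsnp_p	phdsnp_label	panther_p	panther_label	snpsgo_p	snpsgo_label
rs76722191	V322E	V322E	0.718	Disease	0.712	Disease	0.716	Disease
rs121965021	P533R	P533R	0.635	Disease	0.827	Disease	0.671	Disease
rs121965029	R89Q	R89Q	0.841	Disease	0.609	Disease	0.745	Disease
rs121965033	L346R	L346R	0.76	Disease	0.792	Disease	0.663	Disease
rs148789453	L238Q	L238Q	0.777	Disease	0.553	Disease	0.513	Disease
rs200448421	R628P	R628P	0.817	Disease	0.529	Disease	0.634	Disease
rs368454909	D349N	D349N	0.723	Disease	0.603	Disease	0.54	Disease
rs369090960	G265R	G265R	0.12	Disease	0.841	Disease	0.63	Disease
rs371397270	D349G	D349G	0.754	Disease	0.663	Disease	0.593	Disease
rs373037758	L256P	L256P	0.881	Disease	0.795	Disease	0.801	Disease
rs374779600	P533S	P533S	0.539	Disease	0.718	Disease	0.579	Disease
rs587779401	Y625C	Y625C	0.722	Disease	0.867	Disease	0.724	Disease
rs748239393	F287C	F287C	0.668	Disease	0.862	Disease	0.628	Disease
rs750496798	R363C	R363C	0.764	Disease	0.903	Disease	0.701	Disease
rs753308650	G168R	G168R	0.91	Disease	0.841	Disease	0.846	Disease
rs754154200	E182K	E182K	0.772	Disease	0.591	Disease	0.702	Disease
rs754876066	T194P	T194P	0.747	Disease	0.732	Disease	0.628	Disease
rs757706461	P183S	P183S	0.619	Disease	0.718	Disease	0.602	Disease
rs762623046	R166T	R166T	0.739	Disease	0.547	Disease	0.639	Disease
rs772416503	P496R	P496R	0.606	Disease	0.827	Disease	0.568	Disease
rs773908263	P81S	P81S	0.725	Disease	0.688	Disease	0.667	Disease
rs775542391	L114R	L114R	0.818	Disease	0.786	Disease	0.743	Disease
rs775816150	T374P	T374P	0.771	Disease	0.732	Disease	0.538	Disease
rs780165694	Y76C	Y76C	0.646	Disease	0.703	Disease	0.522	Disease
rs794726877	G51D	G51D	0.74	Disease	0.79	Disease	0.704	Disease
rs875989946	W175R	W175R	0.866	Disease	0.839	Disease	0.831	Disease
rs767140903	P302R	P302R	0.673	Disease	0.827	Disease	0.678	Disease
rs375819348	P493R	P493R	0.681	Disease	0.827	Disease	0.633	Disease
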