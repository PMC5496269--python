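mutation	mutation_printed	class	severities	low_reliability	source
134del12	134del12	deletion_insertion	severe	false	splice_indel
c.1147dupG	c.1147dupG	deletion_insertion	severe	false	splice_indel
IVS4-1G>A	IVS4-1G > A	splicing	intermediate,severe	false	splice_indel
153delC	153delC	deletion_insertion	severe	false	splice_indel
c.1166_1171dup	c.1166_1171dup	deletion_insertion	severe	false	splice_indel
IVS4+1G>A	IVS4 + 1G > A	splicing	intermediate	false	splice_indel
229del3	229del3	deletion_insertion	severe	false	splice_indel
c.1190-1delG	c.1190-1delG	deletion_insertion	severe	false	splice_indel
IVS5-7G>A	IVS5-7G > A	splicing	mild	false	splice_indel
252insC	252insC	deletion_insertion	severe	false	splice_indel
c.1225dupG	c.1225dupG	deletion_insertion	severe	false	splice_indel
IVS5+1G>A	IVS5 + 1G > A	splicing	severe	false	splice_indel
c.349delT	c.349delT	deletion_insertion	unknown	false	splice_indel
c.1244-1271del27	c.1244-1271del27	deletion_insertion	severe	false	splice_indel
IVS6+1G>C	IVS6 + 1G > C	splicing	severe	false	splice_indel
396insAC	396insAC	deletion_insertion	mild	true	splice_indel
1251delC	1251delC	deletion_insertion	severe	false	splice_indel
IVS6+1G>T	IVS6 + 1G > T	splicing	severe	false	splice_indel
468del3	468del3	deletion_insertion	severe	false	splice_indel
1277ins9	1277ins9	deletion_insertion	severe	false	splice_indel
IVS7-4G>A	IVS7-4G > A	splicing	severe	false	splice_indel
486del6	486del6	deletion_insertion	unknown	false	splice_indel
1352delG	1352delG	deletion_insertion	severe	false	splice_indel
IVS7+2T>C	IVS7 + 2 T > C	splicing	unknown	false	splice_indel
c.574delT	c.574delT	deletion_insertion	severe	false	splice_indel
c.1398delC	c.1398delC	deletion_insertion	severe	false	splice_indel
IVS8-1G>A	IVS8-1G > A	splicing	severe	false	splice_indel
628del5	628del5	deletion_insertion	severe	false	splice_indel
c.1589insGC	c.1589insGC	deletion_insertion	severe	false	splice_indel
IVS8+4G>A	IVS8 + 4G > A	splicing	intermediate	false	splice_indel
c.657dupG	c.657dupG	deletion_insertion	severe	false	splice_indel
c.1593delG	c.1593delG	deletion_insertion	intermediate	true	splice_indel
IVS8+5G>A	IVS8 + 5G > A	splicing	intermediate,severe	false	splice_indel
668insGCG	668insGCG	deletion_insertion	severe	false	splice_indel
1702delG	1702delG	deletion_insertion	severe	false	splice_indel
IVS9+1G>T	IVS9 + 1G > T	splicing	severe	false	splice_indel
682insAC	682insAC	deletion_insertion	severe	false	splice_indel
1783del11	1783del11	deletion_insertion	severe	false	splice_indel
IVS9+2T>G	IVS9 + 2 T > G	splicing	unknown	false	splice_indel
702ins10del22	702ins10del22	deletion_insertion	severe	false	splice_indel
c.1805delTinsGAACA	c.1805delTinsGAACA	deletion_insertion	severe	false	splice_indel
IVS11-G>T	IVS11-G > T	splicing	severe	false	splice_indel
704ins5	704ins5	deletion_insertion	severe	false	splice_indel
1839del29	1839del29	deletion_insertion	severe	false	splice_indel
IVS11+5G>A	IVS11 + 5G > A	splicing	severe	false	splice_indel
740delC	740delC	deletion_insertion	severe	false	splice_indel
1902del2	1902del2	deletion_insertion	severe	false	splice_indel
IVS11+5G>C	IVS11 + 5G > C	splicing	severe	false	splice_indel
747delG	747delG	deletion_insertion	severe	false	splice_indel
c.1918_1927del10	c.1918_1927del10	deletion_insertion	intermediate	true	splice_indel
3308del12	3308del12	splicing	intermediate	false	splice_indel
755del5	755del5	deletion_insertion	severe	false	splice_indel
1995del11	1995del11	deletion_insertion	intermediate	true	splice_indel
IVS12+1G>A	IVS12 + 1G > A	splicing	severe	false	splice_indel
c.826_828del3	c.826_828del3	deletion_insertion	severe	false	splice_indel
D444/445	D444/445	deletion_insertion	mild	false	splice_indel
IVS12+2T>G	IVS12 + 2 T > G	splicing	severe	false	splice_indel
c.854delC	c.854delC	deletion_insertion	severe	false	splice_indel
c.1-2C>G	c.1-2C > G	splicing	severe	false	splice_indel
IVS12+2T>A	IVS12 + 2 T > A	splicing	unknown	false	splice_indel
c.883dupC	c.883dupC	deletion_insertion	severe	false	splice_indel
IVS2-1G>C	IVS2-1G > C	splicing	severe	false	splice_indel
IVS12+3G>C	IVS12 + 3G > C	splicing	severe	false	splice_indel
c.956_972+9delinsTA	c.956_972 + 9delinsTA	deletion_insertion	severe	false	splice_indel
IVS2-3C>G	IVS2-3C > G	splicing	unknown	false	splice_indel
IVS12+4C>T	IVS12 + 4C > T	splicing	intermediate	false	splice_indel
964delC	964delC	deletion_insertion	severe	false	splice_indel
IVS2+1G>A	IVS2 + 1G > A	splicing	intermediate	false	splice_indel
IVS12+5G>A	IVS12 + 5G > A	splicing	severe	false	splice_indel
974ins12	974ins12	deletion_insertion	mild	false	splice_indel
IVS2+6C>T	IVS2 + 6C > T	splicing	severe	false	splice_indel
IVS12+5G>C	IVS12 + 5G > C	splicing	unknown	false	splice_indel
c.1045_1047del3	c.1045_1047del3	deletion_insertion	severe	false	splice_indel
IVS3-2A>G	IVS3-2A > G	splicing	severe	false	splice_indel
IVS12+6T>A	IVS12 + 6 T > A	splicing	severe	false	splice_indel
1132del6	1132del6	deletion_insertion	severe	false	splice_indel
IVS3+1G>A	IVS3 + 1G > A	splicing	severe	false	splice_indel
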