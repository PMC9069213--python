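# hg19 autosomal chromosome arms (0-based half-open; cytoBand acen boundaries)
chr1	0	121535434	p
chr1	124535434	249250621	q
chr2	0	92326171	p
chr2	95326171	243199373	q
chr3	0	90504854	p
chr3	93504854	198022430	q
chr4	0	49660117	p
chr4	52660117	191154276	q
chr5	0	46405641	p
chr5	49405641	180915260	q
chr6	0	58830166	p
chr6	61830166	171115067	q
chr7	0	58054331	p
chr7	61054331	159138663	q
chr8	0	43838887	p
chr8	46838887	146364022	q
chr9	0	47367679	p
chr9	50367679	141213431	q
chr10	0	39254935	p
chr10	42254935	135534747	q
chr11	0	51644205	p
chr11	54644205	135006516	q
chr12	0	34856694	p
chr12	37856694	133851895	q
chr13	0	16000000	p
chr13	19000000	115169878	q
chr14	0	16000000	p
chr14	19000000	107349540	q
chr15	0	17000000	p
chr15	20000000	102531392	q
chr16	0	35335801	p
chr16	38335801	90354753	q
chr17	0	22263006	p
chr17	25263006	81195210	q
chr18	0	15460898	p
chr18	18460898	78077248	q
chr19	0	24681782	p
chr19	27681782	59128983	q
chr20	0	26369569	p
chr20	29369569	63025520	q
chr21	0	11288129	p
chr21	14288129	48129895	q
chr22	0	13000000	p
chr22	16000000	51304566	q
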