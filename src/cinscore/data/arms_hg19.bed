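# build=hg19 coordinates=0-based-half-open
# Autosomal chromosome-arm intervals; arm boundaries at the UCSC hg19
# centromere gap. Columns: chrom, start, end, arm_label.
1	0	121535434	1p
1	124535434	249250621	1q
2	0	92326171	2p
2	95326171	243199373	2q
3	0	90504854	3p
3	93504854	198022430	3q
4	0	49660117	4p
4	52660117	191154276	4q
5	0	46405641	5p
5	49405641	180915260	5q
6	0	58830166	6p
6	61830166	171115067	6q
7	0	58054331	7p
7	61054331	159138663	7q
8	0	43838887	8p
8	46838887	146364022	8q
9	0	47367679	9p
9	50367679	141213431	9q
10	0	39254935	10p
10	42254935	135534747	10q
11	0	51644205	11p
11	54644205	135006516	11q
12	0	34856694	12p
12	37856694	133851895	12q
13	0	16000000	13p
13	19000000	115169878	13q
14	0	16000000	14p
14	19000000	107349540	14q
15	0	17000000	15p
15	20000000	102531392	15q
16	0	35335801	16p
16	38335801	90354753	16q
17	0	22263006	17p
17	25263006	81195210	17q
18	0	15460898	18p
18	18460898	78077248	18q
19	0	24681782	19p
19	27681782	59128983	19q
20	0	26369569	20p
20	29369569	63025520	20q
21	0	11288129	21p
21	14288129	48129895	21q
22	0	13000000	22p
22	16000000	51304566	22q
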