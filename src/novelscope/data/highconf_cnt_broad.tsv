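gene_id	transcript_id	coordinates	length	strand	ps	ns
MSTRG.10752	MSTRG.10752.1	16:91113662-91114155	493	.	0.997	100
MSTRG.11071	MSTRG.11071.1	17:16557283-16557630	347	.	0.997	100
MSTRG.11709	MSTRG.11709.2	17:39636629-39637143	514	-	0.997	100
MSTRG.13417	MSTRG.13417.2	19:17926989-17927998	1009	+	0.993	100
MSTRG.9039	MSTRG.9039.1	15:31655084-31655385	301	.	0.990	100
MSTRG.17446	MSTRG.17446.1	3:104752371-104752702	331	-	0.989	100
MSTRG.30048	MSTRG.30048.1	X:146176602-146177068	466	+	0.989	100
MSTRG.12849	MSTRG.12849.1	18:64611849-64612445	596	-	0.989	100
MSTRG.1816	MSTRG.1816.1	1:178299808-178300378	570	+	0.987	100
MSTRG.18663	MSTRG.18663.1	4:83421622-83422080	458	-	0.987	100
MSTRG.6455	MSTRG.6455.1	12:102866597-102867299	702	.	0.984	100
MSTRG.12840	MSTRG.12840.1	18:63543865-63545205	1340	+	0.981	100
MSTRG.21639	MSTRG.21639.1	5:127954976-127955377	401	.	0.978	100
MSTRG.8143	MSTRG.8143.1	14:33428605-33429024	419	.	0.973	100
MSTRG.13495	MSTRG.13495.1	19:25346816-25347223	407	.	0.973	100
MSTRG.15865	MSTRG.15865.1	2:157528311-157528617	306	.	0.970	100
MSTRG.20543	MSTRG.20543.1	5:46415104-46415426	322	+	0.970	100
MSTRG.6330	MSTRG.6330.1	12:86845755-86846203	448	.	0.970	100
MSTRG.8249	MSTRG.8249.1	14:48695580-48695978	398	.	0.969	100
MSTRG.7535	MSTRG.7535.1	13:91260953-91262729	1776	+	0.969	100
MSTRG.18684	MSTRG.18684.1	4:87103424-87105078	1654	+	0.967	100
MSTRG.18685	MSTRG.18685.1	4:87103426-87105078	1652	-	0.967	100
MSTRG.6715	MSTRG.6715.1	13:8289064-8289370	306	.	0.966	100
MSTRG.7905	MSTRG.7905.1	14:15949235-15949774	539	.	0.965	100
MSTRG.7913	MSTRG.7913.1	14:16451876-16452185	309	.	0.953	100
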