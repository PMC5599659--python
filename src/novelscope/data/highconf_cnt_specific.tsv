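gene_id	transcript_id	coordinates	length	strand	ps	ns
MSTRG.16504	MSTRG.16504.1	3:36117033-36117334	301	.	1.000	100
MSTRG.18476	MSTRG.18476.1	4:53663579-53663885	306	.	0.993	100
MSTRG.12840	MSTRG.12840.2	18:63543888-63544690	802	+	0.989	100
MSTRG.444	MSTRG.444.1	1:52585218-52585601	383	.	0.988	100
MSTRG.7901	MSTRG.7901.1	14:14447656-14448019	363	.	0.982	100
MSTRG.25445	MSTRG.25445.1	7:127398616-127399037	421	.	0.980	100
MSTRG.3390	MSTRG.3390.1	10:129665538-129665871	333	.	0.975	100
MSTRG.6084	MSTRG.6084.1	12:72048695-72049032	337	.	0.975	100
MSTRG.10567	MSTRG.10567.1	16:53985023-53985331	308	.	0.973	100
MSTRG.10245	MSTRG.10245.1	16:23050282-23050873	591	.	0.973	100
MSTRG.6777	MSTRG.6777.2	13:15119006-15119437	431	+	0.970	100
MSTRG.26441	MSTRG.26441.1	8:72283729-72284163	434	.	0.969	100
MSTRG.10714	MSTRG.10714.1	16:88682165-88682703	538	.	0.966	100
MSTRG.25152	MSTRG.25152.1	7:107951379-107951776	397	.	0.963	100
MSTRG.14539	MSTRG.14539.1	2:34648981-34649511	530	-	0.956	100
MSTRG.6778	MSTRG.6778.2	13:15118406-15118934	528	+	0.956	100
MSTRG.13452	MSTRG.13452.1	19:23166931-23168119	1188	.	0.956	100
MSTRG.12890	MSTRG.12890.1	18:67920731-67921163	432	.	0.955	100
MSTRG.13017	MSTRG.13017.1	18:90311445-90311766	321	.	0.952	100
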