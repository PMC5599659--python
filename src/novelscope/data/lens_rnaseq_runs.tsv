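sra_id	stage	read_type	read_length	n_reads	base_count	alignment_pct
SRR2039769	E15	PE	100	13772390	2754478000	94
SRR2039770	E15	PE	100	13542500	2708500000	95
SRR953395	E15.5	SE	52	48552190	2524713880	94
SRR953394	E15.5	SE	52	47574424	2473870048	94
SRR953393	E15.5	SE	52	42525381	2211319812	94
SRR2039771	E18	PE	100	17810970	3562194000	93
SRR2039772	E18	PE	100	18019388	3603877600	93
SRR2039773	P0	PE	100	17766309	3553261800	93
SRR2039774	P0	PE	100	14533000	2906600000	93
SRR2039775	P3	PE	100	15495833	3099166600	93
SRR2039776	P3	PE	100	13072393	2614478600	93
SRR2039777	P6	PE	100	16965754	3393150800	93
SRR2039778	P6	PE	100	17658286	3531657200	93
SRR2039779	P9	PE	100	18874309	3774861800	93
SRR2039780	P9	PE	100	13563853	2712770600	93
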