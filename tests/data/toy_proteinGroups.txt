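Protein IDs	Gene names	Reverse	Potential contaminant	Only identified by site	Score	LFQ intensity t_UT_1	LFQ intensity t_UT_2	LFQ intensity t_UT_3	LFQ intensity t_UT_4	LFQ intensity t_Ti_1	LFQ intensity t_Ti_2	LFQ intensity t_Ti_3	LFQ intensity t_Ti_4
P01;P01-ALT	GP01				100.5	1048576.0	1048576.0	1048576.0	1048576.0	4194304.0	4194304.0	2097152.0	8388608.0
P02;P02-ALT	GP02				100.5	33554432.0	47453132.8121	23726566.4061	33554432.0	16777216.0	11863283.203	23726566.4061	16777216.0
P03;P03-ALT	GP03				100.5	4194304.0	4817990.1052	3651353.7098	4194304.0	4495343.721	3913424.0085	4194304.0	4194304.0
P04;P04-ALT	GP04				100.5	262144.0	370727.6001	185363.8	262144.0	301124.3816	228209.6069	262144.0	345901.0818
P05;P05-ALT	GP05				100.5	67108864.0	67108864.0	67108864.0	67108864.0	67108864.0	67108864.0	67108864.0	67108864.0
P06;P06-ALT	GP06				100.5	2097152.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
P07;P07-ALT	GP07				100.5	0.0	0.0	0.0	0.0	524288.0	0.0	0.0	0.0
P08;P08-ALT	GP08				100.5	8388608.0	8990687.442	7826848.0171	8388608.0	8388608.0	9635980.2103	7302707.4197	8388608.0
P09;P09-ALT	GP09				100.5	16777216.0	16777216.0	23726566.4061	11863283.203	16777216.0	19271960.4206	14605414.8393	16777216.0
P10;P10-ALT	GP10		+		100.5	1048576.0	1048576.0	1048576.0	1048576.0	1048576.0	1048576.0	1048576.0	1048576.0
P11;P11-ALT	GP11	+			100.5	2097152.0	2097152.0	2097152.0	2097152.0	2097152.0	2097152.0	2097152.0	2097152.0
P12;P12-ALT	GP12			+	100.5	4194304.0	4194304.0	4194304.0	4194304.0	4194304.0	4194304.0	4194304.0	4194304.0
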