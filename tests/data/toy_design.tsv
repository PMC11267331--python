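sample_id	batch	condition	donor	replicate
t_UT_1	term	UT	1	1
t_UT_2	term	UT	2	2
t_UT_3	term	UT	3	3
t_UT_4	term	UT	4	4
t_Ti_1	term	TiO2	1	1
t_Ti_2	term	TiO2	2	2
t_Ti_3	term	TiO2	3	3
t_Ti_4	term	TiO2	4	4
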