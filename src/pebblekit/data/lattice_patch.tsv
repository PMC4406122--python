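vertices	8
0	1	quenched	5	1
0	4	fluctuating	5	1
1	2	fluctuating	5	1
1	5	quenched	5	1
2	3	quenched	5	1
2	6	quenched	5	1
5	6	quenched	5	1
6	7	fluctuating	5	1
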