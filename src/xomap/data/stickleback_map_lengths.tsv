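chromosome	female_cM	male_cM
1	112.5	83.3
2	95.8	43.3
3	62.5	50.0
4	133.3	83.3
5	70.8	46.7
6	70.8	40.0
7	87.5	83.3
8	62.5	43.3
9	83.3	46.7
10	70.8	33.3
11	62.5	50.0
12	91.7	50.0
13	79.2	46.7
14	54.2	30.0
15	45.8	36.7
16	83.3	43.3
17	87.5	46.7
18	70.8	13.3
19	91.7	43.3
20	70.8	43.3
21	62.5	50.0
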