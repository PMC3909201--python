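i	j	r0
1	5	6.202842
1	26	6.018948
1	27	4.318493
2	6	6.202842
2	26	7.898437
2	27	4.700590
3	7	6.202842
4	8	6.202842
4	26	9.082852
4	27	7.977862
5	9	6.202842
5	23	6.240890
5	24	7.864153
5	26	8.099734
5	27	6.816912
6	10	6.202842
7	11	6.202842
8	12	6.202842
15	19	8.147038
16	20	6.202842
17	21	6.202842
18	22	6.202842
19	23	6.202842
20	24	6.202842
21	25	6.202842
22	26	6.202842
23	27	6.202842
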