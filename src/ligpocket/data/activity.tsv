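compound_id	series	pde4b1_nM	pde4a4_nM	pde4d3_nM	harbs_nM	tnfa_hwb_nM	tnfa_hpbmc_nM	caco2_nM	mned_mgkg
Roflumilast	reference	nd	nd	nd	nd	nd	nd	39	0.3
Rolipram	reference	nd	nd	nd	nd	nd	nd	nd	nd
2a	2	29.01	4.7	5.23	nd	38.22	nd	nd	nd
2b	2	nd	nd	nd	nd	nd	nd	nd	nd
2c	2	nd	nd	nd	nd	nd	nd	nd	nd
2d	2	nd	nd	nd	nd	nd	nd	nd	nd
2e	2	nd	nd	nd	nd	nd	nd	nd	nd
2f	2	0.73	40.01	17.0	190.02	3.7	nd	nd	nd
2g	2	229.21	nd	nd	nd	nd	nd	nd	nd
2h	2	2998.01	nd	nd	nd	nd	nd	nd	nd
2i	2	907.02	nd	nd	nd	nd	nd	nd	nd
2j	2	nd	nd	nd	nd	nd	nd	nd	nd
2k	2	nd	nd	nd	nd	nd	nd	nd	nd
2l	2	nd	nd	nd	nd	nd	nd	nd	nd
2m	2	nd	nd	nd	nd	nd	nd	nd	nd
2n	2	9.24	nd	6.02	52.04	320.11	nd	nd	nd
2o	2	6700	nd	nd	nd	nd	nd	nd	nd
2p	2	1.41	nd	nd	nd	239.23	nd	nd	nd
2q	2	20.06	nd	nd	nd	61.03	nd	nd	nd
2r	2	nd	nd	nd	nd	nd	nd	nd	nd
2s	2	nd	nd	nd	nd	nd	nd	nd	nd
2t	2	7.20	nd	nd	nd	nd	nd	nd	nd
2u	2	nd	nd	nd	nd	nd	nd	nd	nd
2v	2	nd	nd	nd	nd	nd	nd	nd	nd
2w	2	nd	nd	nd	16.24	17.01	nd	nd	nd
3a	3	19.54	nd	nd	nd	nd	nd	39	2.7
3b	3	nd	nd	nd	nd	nd	nd	nd	nd
3c	3	nd	nd	nd	nd	nd	nd	nd	nd
3d	3	nd	nd	nd	nd	nd	nd	nd	nd
3e	3	nd	nd	nd	nd	nd	nd	nd	nd
3f	3	0.36	nd	nd	5.10	2.40	nd	nd	nd
3g	3	0.73	nd	nd	120.32	220.0	nd	nd	nd
3h	3	nd	nd	nd	nd	nd	nd	nd	nd
3i	3	nd	nd	nd	nd	nd	nd	nd	nd
3j	3	nd	nd	nd	nd	5.97	nd	nd	nd
3k	3	nd	nd	nd	nd	nd	nd	45	1.1
3l	3	nd	nd	nd	nd	nd	nd	nd	nd
4a	4	nd	nd	nd	nd	nd	nd	nd	nd
4b	4	nd	nd	nd	nd	nd	nd	nd	nd
4c	4	nd	nd	nd	nd	nd	nd	nd	nd
4d	4	nd	nd	nd	nd	nd	nd	nd	nd
4e	4	nd	nd	nd	nd	nd	nd	nd	nd
4f	4	nd	nd	nd	nd	nd	nd	nd	nd
4g	4	nd	nd	nd	nd	nd	nd	nd	nd
5a	5	nd	nd	nd	nd	nd	nd	nd	nd
5b	5	nd	nd	nd	nd	nd	nd	nd	nd
5c	5	nd	nd	nd	nd	nd	nd	nd	nd
5d	5	5200	nd	nd	nd	nd	nd	nd	nd
5e	5	nd	nd	nd	nd	nd	nd	nd	nd
5f	5	nd	nd	nd	nd	nd	nd	nd	nd
5g	5	113.04	nd	nd	nd	nd	nd	nd	nd
5h	5	181.23	nd	nd	nd	nd	nd	nd	nd
5i	5	82.51	nd	nd	nd	nd	nd	nd	nd
5j	5	1200.03	nd	nd	nd	nd	nd	nd	nd
5k	5	nd	nd	nd	nd	nd	nd	nd	nd
5l	5	nd	nd	nd	nd	nd	nd	nd	nd
7	other	nd	nd	nd	nd	nd	nd	nd	nd
9	other	nd	nd	nd	nd	nd	nd	nd	nd
10a	other	nd	nd	nd	nd	nd	nd	nd	nd
10b	other	nd	nd	nd	nd	nd	nd	nd	nd
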