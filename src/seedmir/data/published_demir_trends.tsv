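mirna_id	tendency	MpSI-1	MpSI-2	MpSI-3	MpSII-1	MpSII-2	MpSII-3	MpSIII-1	MpSIII-2	MpSIII-3	log2fc_II_vs_I	log2fc_III_vs_II
mpi-miR156f-5p	same	0	0	0	2	2	4	12	13	12	7.65	1.74
mpi-miR482a-3p	same	2380	4221	2288	5869	5817	7435	39410	19325	18703	1.58	1.49
mpi-nmiR0004-3p	same	21	20	9	25	22	24	69	80	106	1.07	1.28
mpi-nmiR0083-3p	same	0	0	0	11	11	9	71	70	84	9.71	2.28
mpi-nmiR0119-5p	same	0	0	0	2	2	6	10	8	14	7.92	1.26
mpi-miR156a-3p	same	2112	3098	1195	736	356	577	316	347	424	-1.39	-1.19
mpi-miR164a-5p	same	141	121	130	7	20	32	11	7	7	-2.37	-1.67
mpi-miR166a-5p	same	3344	2597	2102	718	822	1330	437	495	803	-1.03	-1.22
mpi-miR166k-5p	same	408	297	290	19	21	30	7	4	9	-3.37	-2.32
mpi-miR171j-5p	same	66	54	35	5	5	5	0	2	0	-2.83	-3.43
mpi-miR393b-5p	same	384	272	219	44	84	133	35	38	42	-1.31	-1.64
mpi-miR399a-3p	same	5907	4743	3838	908	1026	1399	725	552	741	-1.65	-1.24
mpi-miR399b-3p	same	3876	4196	2814	1094	848	1048	412	207	306	-1.35	-2.25
mpi-miR156c-5p	opposite	84	111	69	327	203	197	95	68	83	2.01	-2.16
mpi-miR168d-3p	opposite	0	0	0	2	4	9	0	0	0	8.49	-8.49
mpi-miR171b-3p	opposite	96	94	52	170	226	432	219	142	198	2.22	-1.02
mpi-miR398c-3p	opposite	393	398	260	964	1092	1553	360	317	436	2.25	-2.21
mpi-miR398f-3p	opposite	10	10	6	113	142	169	9	7	13	4.52	-4.40
mpi-miR408a-3p	opposite	130	137	75	379	446	612	176	170	199	2.56	-1.91
mpi-miR408b-3p	opposite	15	15	6	68	98	147	35	45	59	3.62	-1.66
mpi-miR408d-3p	opposite	7	8	8	84	63	76	37	54	45	3.75	-1.28
mpi-miR4403-5p	opposite	3	3	3	6	5	6	2	2	2	1.39	-2.06
mpi-miR5037	opposite	0	0	0	2	2	2	0	0	0	7.32	-7.32
mpi-nmiR0028-3p	opposite	7	6	7	25	32	19	7	7	3	2.44	-2.75
mpi-nmiR0034-3p	opposite	4	5	3	6	6	9	4	2	3	1.28	-1.73
mpi-nmiR0050-5p	opposite	0	0	0	5	3	6	0	0	0	8.50	-8.50
mpi-nmiR0072-5p	opposite	14	25	12	16	28	47	2	8	5	1.25	-3.06
mpi-nmiR0103-5p	opposite	0	0	0	4	16	10	0	0	0	9.63	-9.63
mpi-miR396c-3p	opposite	1094	422	725	69	78	151	401	240	257	-2.50	1.13
mpi-miR396e-5p	opposite	9	8	4	0	0	0	5	3	5	-8.57	7.88
mpi-miR399d-3p	opposite	43	33	29	0	0	0	5	7	2	-10.94	7.99
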