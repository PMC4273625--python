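roi_id	mni_x	mni_y	mni_z	dosenbach_label	system	aal_name	community_vlf	community_lf
1	6	64	3	vmPFC	default	Frontal_Sup_Medial_R	1	1
2	0	51	32	mPFC	default	Frontal_Sup_Medial_L	1	1
3	-25	51	27	aPFC	default	Frontal_Mid_L	1	2
4	9	51	16	vmPFC	default	Cingulum_Ant_R	1	1
5	-6	50	-1	vmPFC	default	Cingulum_Ant_L	1	1
6	-11	45	17	vmPFC	default	Frontal_Sup_Medial_L	1	1
7	8	42	-5	vmPFC	default	Cingulum_Ant_R	3	3
8	9	39	20	ACC	default	Cingulum_Ant_R	3	3
9	46	39	-15	vlPFC	default	Frontal_Inf_Orb_R	1	2
10	23	33	47	Sup frontal	default	Frontal_Sup_R	1	2
11	-16	29	54	Sup frontal	default	Frontal_Sup_L	1	1
12	52	-15	-13	Inf temporal	default	Temporal_Mid_R	1	1
13	-59	-25	-15	Inf temporal	default	Temporal_Mid_L	1	1
14	1	-26	31	Post-cingulate	default	Cingulum_Mid_R	2	3
15	28	-37	-15	Fusiform	default	Fusiform_R	1	1
16	-3	-38	45	Precuneus	default	Cingulum_Mid_L	1	1
17	-8	-41	3	Post-ingulate	default	Calcarine_L	1	1
18	-61	-41	-2	Inf temporal	default	Temporal_Mid_L	1	1
19	-28	-42	-11	Occipital	default	Lingual_L	1	1
20	-5	-43	25	Post-cungulate	default	Cingulum_Post_L	1	1
21	9	-43	25	Precuneus	default	Cingulum_Post_R	1	1
22	5	-50	33	Precuneus	default	Precuneus_R	1	1
23	-5	-52	17	Post-cungulate	default	Precuneus_L	1	1
24	10	-55	17	Post-cungulate	default	Precuneus_R	1	1
25	-6	-56	29	Precuneus	default	Precuneus_L	1	1
26	-11	-58	17	Post-cungulate	default	Cuneus_L	1	1
27	51	-59	34	Angular gyrus	default	Angular_R	1	2
28	-48	-63	35	Angular gyrus	default	Angular_L	1	1
29	11	-68	42	Precuneus	default	Precuneus_R	2	2
30	-36	-69	40	IPS	default	Parietal_Inf_L	1	1
31	-9	-72	41	Occipital	default	Precuneus_L	2	1
32	45	-72	29	Occipital	default	Occipital_Mid_R	1	2
33	-2	-75	32	Occipital	default	Cuneus_L	1	1
34	-42	-76	26	Occipital	default	Occipital_Mid_L	1	1
35	29	57	18	aPFC	fronto-parietal	Frontal_Mid_R	3	3
36	-29	57	10	aPFC	fronto-parietal	Frontal_Mid_L	3	3
37	42	48	-3	vent aPFC	fronto-parietal	Frontal_Inf_Tri_R	2	3
38	-43	47	2	vent aPFC	fronto-parietal	Frontal_Inf_Tri_L	2	2
39	39	42	16	vlPFC	fronto-parietal	Frontal_Mid_R	2	3
40	40	36	29	dlPFC	fronto-parietal	Frontal_Mid_R	2	2
41	-1	28	40	ACC	fronto-parietal	Frontal_Sup_Medial_L	3	3
42	46	28	31	dlPFC	fronto-parietal	Frontal_Mid_R	2	2
43	-52	28	17	vPFC	fronto-parietal	Frontal_Inf_Tri_L	2	2
44	-44	27	33	dlPFC	fronto-parietal	Frontal_Mid_L	2	2
45	40	17	40	dFC	fronto-parietal	Frontal_Mid_R	1	2
46	44	8	34	dFC	fronto-parietal	Precentral_R	2	2
47	-42	7	36	dFC	fronto-parietal	Precentral_L	1	2
48	-41	-40	42	IPL	fronto-parietal	Parietal_Inf_L	2	2
49	54	-44	43	IPL	fronto-parietal	Parietal_Inf_R	2	2
50	-35	-46	48	Post-parietal	fronto-parietal	Parietal_Inf_L	2	2
51	-48	-47	49	IPL	fronto-parietal	Parietal_Inf_L	2	2
52	-53	-50	39	IPL	fronto-parietal	Parietal_Inf_L	2	2
53	44	-52	47	IPL	fronto-parietal	Parietal_Inf_R	2	2
54	-32	-58	46	IPS	fronto-parietal	Parietal_Inf_L	2	2
55	32	-59	41	IPS	fronto-parietal	Angular_R	2	2
56	27	49	26	aPFC	cingulo-opercular	Frontal_Mid_R	3	3
57	34	32	7	vPFC	cingulo-opercular	Frontal_Inf_Tri_R	2	3
58	-2	30	27	ACC	cingulo-opercular	Cingulum_Mid_L	3	3
59	51	23	8	vFC	cingulo-opercular	Frontal_Inf_Tri_R	1	2
60	38	21	-1	Ant insula	cingulo-opercular	Insula_R	3	3
61	9	20	34	dACC	cingulo-opercular	Cingulum_Mid_R	3	3
62	-36	18	2	Ant insula	cingulo-opercular	Insula_L	3	3
63	-6	17	34	Basal ganglia	cingulo-opercular	Cingulum_Mid_L	3	3
64	0	15	45	mFC	cingulo-opercular	Supp_Motor_Area_L	3	3
65	-46	10	14	vFC	cingulo-opercular	Rolandic_Oper_L	2	2
66	-20	6	7	Basal ganglia	cingulo-opercular	Putamen_L	3	3
67	14	6	7	Basal ganglia	cingulo-opercular	Caudate_R	3	3
68	-48	6	1	vFC	cingulo-opercular	Insula_L	3	3
69	37	-2	-3	Mid insula	cingulo-opercular	Putamen_R	3	3
70	-12	-3	13	Thalamus	cingulo-opercular	Caudate_L	3	3
71	-12	-12	6	Thalamus	cingulo-opercular	Thalamus_L	3	3
72	11	-12	6	Thalamus	cingulo-opercular	Thalamus_R	3	3
73	32	-12	2	Mid insula	cingulo-opercular	Putamen_R	3	3
74	-30	-14	1	Mid insula	cingulo-opercular	Putamen_L	3	3
75	11	-24	2	Basal ganglia	cingulo-opercular	Thalamus_R	3	3
76	-30	-28	9	Post-insula	cingulo-opercular	Heschl_L	3	3
77	51	-30	5	Temporal	cingulo-opercular	Temporal_Sup_R	1	1
78	-4	-31	-4	Post-cungulate	cingulo-opercular	Thalamus_L	3	3
79	54	-31	-18	Fusiform	cingulo-opercular	Temporal_Mid_R	1	1
80	8	-40	50	Precuneus	cingulo-opercular	Precuneus_R	1	3
81	58	-41	20	Parietal	cingulo-opercular	Temporal_Sup_R	1	1
82	43	-43	8	Temporal	cingulo-opercular	Temporal_Mid_R	1	1
83	-55	-44	30	Parietal	cingulo-opercular	SupraMarginal_L	2	2
84	42	-46	21	Sup temporal	cingulo-opercular	Angular_R	1	1
85	-41	-47	29	Angular gyrus	cingulo-opercular	Angular_L	1	2
86	-59	-47	11	Temporal	cingulo-opercular	Temporal_Mid_L	1	1
87	-52	-63	15	TPJ	cingulo-opercular	Temporal_Mid_L	1	1
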