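label,name,lobe
1,Precentral_L,frontal
2,Precentral_R,frontal
3,Frontal_Sup_L,frontal
4,Frontal_Sup_R,frontal
5,Frontal_Sup_Orb_L,frontal
6,Frontal_Sup_Orb_R,frontal
7,Frontal_Mid_L,frontal
8,Frontal_Mid_R,frontal
9,Frontal_Mid_Orb_L,frontal
10,Frontal_Mid_Orb_R,frontal
11,Frontal_Inf_Oper_L,frontal
12,Frontal_Inf_Oper_R,frontal
13,Frontal_Inf_Tri_L,frontal
14,Frontal_Inf_Tri_R,frontal
15,Frontal_Inf_Orb_L,frontal
16,Frontal_Inf_Orb_R,frontal
17,Rolandic_Oper_L,frontal
18,Rolandic_Oper_R,frontal
19,Supp_Motor_Area_L,frontal
20,Supp_Motor_Area_R,frontal
21,Olfactory_L,frontal
22,Olfactory_R,frontal
23,Frontal_Sup_Medial_L,frontal
24,Frontal_Sup_Medial_R,frontal
25,Frontal_Med_Orb_L,frontal
26,Frontal_Med_Orb_R,frontal
27,Rectus_L,frontal
28,Rectus_R,frontal
29,Insula_L,other
30,Insula_R,other
31,Cingulum_Ant_L,other
32,Cingulum_Ant_R,other
33,Cingulum_Mid_L,other
34,Cingulum_Mid_R,other
35,Cingulum_Post_L,other
36,Cingulum_Post_R,other
37,Hippocampus_L,temporal
38,Hippocampus_R,temporal
39,ParaHippocampal_L,temporal
40,ParaHippocampal_R,temporal
41,Amygdala_L,temporal
42,Amygdala_R,temporal
43,Calcarine_L,occipital
44,Calcarine_R,occipital
45,Cuneus_L,occipital
46,Cuneus_R,occipital
47,Lingual_L,occipital
48,Lingual_R,occipital
49,Occipital_Sup_L,occipital
50,Occipital_Sup_R,occipital
51,Occipital_Mid_L,occipital
52,Occipital_Mid_R,occipital
53,Occipital_Inf_L,occipital
54,Occipital_Inf_R,occipital
55,Fusiform_L,temporal
56,Fusiform_R,temporal
57,Postcentral_L,parietal
58,Postcentral_R,parietal
59,Parietal_Sup_L,parietal
60,Parietal_Sup_R,parietal
61,Parietal_Inf_L,parietal
62,Parietal_Inf_R,parietal
63,SupraMarginal_L,parietal
64,SupraMarginal_R,parietal
65,Angular_L,parietal
66,Angular_R,parietal
67,Precuneus_L,parietal
68,Precuneus_R,parietal
69,Paracentral_Lobule_L,parietal
70,Paracentral_Lobule_R,parietal
71,Caudate_L,other
72,Caudate_R,other
73,Putamen_L,other
74,Putamen_R,other
75,Pallidum_L,other
76,Pallidum_R,other
77,Thalamus_L,other
78,Thalamus_R,other
79,Heschl_L,temporal
80,Heschl_R,temporal
81,Temporal_Sup_L,temporal
82,Temporal_Sup_R,temporal
83,Temporal_Pole_Sup_L,temporal
84,Temporal_Pole_Sup_R,temporal
85,Temporal_Mid_L,temporal
86,Temporal_Mid_R,temporal
87,Temporal_Pole_Mid_L,temporal
88,Temporal_Pole_Mid_R,temporal
89,Temporal_Inf_L,temporal
90,Temporal_Inf_R,temporal
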