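# Transcription of the published Table 1: the 90 BRCA2 DNA-binding-domain missense
# variants called non-functional by the HDR assay (upper 95% CI < 1.66), with the
# laboratory's applied ACMG/AMP evidence codes and before/after classifications.
# Note: p.Glu2599Gly prints upper CI 1.66 (rounding of an underlying value < 1.66;
# PS3 is applied to the row). Eight of these variants lie in OB2 (residues 2804-3054):
# 2819x2, 2824, 3003, 3006, 3028, 3052x2; the accompanying text says seven.
hgvs_p	residue	ref_aa	alt_aa	hdr_score	hdr_upper_ci	ps3	pm1	pm5	pp1	pm3	insilico	freq_code	freq_detail	before_class	final_class
p.Ala2603Pro	2603	Ala	Pro	1.07	1.25	PS3	-	-	-	-	-	-	-	N/O	N/O
p.Ala2730Pro	2730	Ala	Pro	1.01	1.15	PS3	PM1_supp	-	PP1	-	inc	-	-	VUS	LP
p.Ala2780Asp	2780	Ala	Asp	1.04	1.21	PS3	-	-	-	-	inc	PM2_supp	-	VUS	VUS
p.Ala2786Pro	2786	Ala	Pro	1.22	1.43	PS3	-	-	-	-	-	-	-	N/O	N/O
p.Ala3028Pro	3028	Ala	Pro	1.18	1.38	PS3	PM1	-	PP1_mod	PM3	BP4	PM2_supp	-	LP	P
p.Ala3122Pro	3122	Ala	Pro	1.09	1.24	PS3	-	-	-	-	-	-	-	N/O	N/O
p.Asp2723Ala	2723	Asp	Ala	0.99	1.15	PS3	PM1	PM5	PP1	-	PP3	PM2_supp	-	LP	P
p.Asp2723Gly	2723	Asp	Gly	0.94	1.10	PS3	-	PM5	-	-	PP3	PM2_supp	-	VUS	P
p.Asp2723His	2723	Asp	His	1.00	1.07	PS3	-	-	-	-	PP3	PM2_supp	-	VUS	P
p.Asp2723Asn	2723	Asp	Asn	0.89	1.04	PS3	PM1	-	-	-	inc	PM2_supp	-	VUS	LP
p.Asp2723Val	2723	Asp	Val	0.98	1.11	PS3	PM1	PM5	PP1	-	PP3	PM2_supp	-	LP	P
p.Asp2723Tyr	2723	Asp	Tyr	1.17	1.36	PS3	-	-	-	-	-	-	-	N/O	N/O
p.Asp2819His	2819	Asp	His	1.37	1.60	PS3	-	-	-	-	-	-	-	N/O	N/O
p.Asp2819Val	2819	Asp	Val	1.20	1.36	PS3	-	-	-	-	inc	PM2_supp	-	VUS	VUS
p.Asp3073Gly	3073	Asp	Gly	1.08	1.26	PS3	-	-	-	-	inc	PM2_supp	-	VUS	VUS
p.Asp3073Tyr	3073	Asp	Tyr	0.98	1.15	PS3	-	-	-	-	inc	PM2_supp	-	VUS	VUS
p.Asp3095Glu	3095	Asp	Glu	0.95	1.07	PS3	PM1	-	-	-	inc	PM2_supp	-	VUS	P
p.Asp3095Gly	3095	Asp	Gly	1.04	1.21	PS3	-	PM5	PP1	-	inc	PM2_supp	-	VUS	P
p.Glu2599Gly	2599	Glu	Gly	1.46	1.66	PS3	-	-	-	-	inc	PM2_supp	-	VUS	VUS
p.Glu2663Lys	2663	Glu	Lys	0.83	0.93	PS3	PM1	-	PP1	-	inc	PM2_supp	-	VUS	P
p.Phe2562Cys	2562	Phe	Cys	1.32	1.54	PS3	-	-	-	-	inc	PM2_supp	-	VUS	VUS
p.Phe2562Val	2562	Phe	Val	1.08	1.26	PS3	-	-	-	-	-	-	-	N/O	N/O
p.Phe2642Ser	2642	Phe	Ser	1.07	1.25	PS3	-	-	-	-	-	-	-	N/O	N/O
p.Phe3146Ser	3146	Phe	Ser	1.06	1.23	PS3	-	-	-	-	inc	PM2_supp	-	VUS	VUS
p.Gly2508Arg	2508	Gly	Arg	1.08	1.26	PS3	-	-	-	-	-	-	-	N/O	N/O
p.Gly2596Glu	2596	Gly	Glu	1.12	1.30	PS3	-	-	-	-	PP3	PM2_supp	-	VUS	LP
p.Gly2596Arg	2596	Gly	Arg	1.28	1.49	PS3	-	-	-	-	PP3	PM2_supp	-	VUS	LP
p.Gly2609Val	2609	Gly	Val	1.07	1.25	PS3	PM1_supp	-	-	-	inc	PM2_supp	-	VUS	LP
p.Gly2724Val	2724	Gly	Val	1.07	1.24	PS3	-	-	-	-	PP3	PM2_supp	-	VUS	LP
p.Gly2724Trp	2724	Gly	Trp	1.12	1.27	PS3	-	-	-	-	-	-	-	N/O	N/O
p.Gly2748Asp	2748	Gly	Asp	0.95	1.08	PS3	-	-	PP1	-	PP3	-	-	VUS	LP
p.Gly2748Ser	2748	Gly	Ser	0.97	1.13	PS3	-	-	-	-	-	-	-	N/O	N/O
p.Gly2793Glu	2793	Gly	Glu	1.19	1.23	PS3	PM1	-	-	-	PP3	PM2_supp	-	VUS	LP
p.Gly2793Arg	2793	Gly	Arg	1.18	1.37	PS3	PM1_supp	PM5	-	-	PP3	-	-	VUS	P
p.Gly2793Val	2793	Gly	Val	1.16	1.32	PS3	-	PM5	-	-	PP3	PM2_supp	-	VUS	P
p.Gly3003Glu	3003	Gly	Glu	1.35	1.57	PS3	-	-	-	-	inc	PM2_supp	-	VUS	VUS
p.Gly3076Glu	3076	Gly	Glu	1.04	1.18	PS3	PM1	-	-	-	PP3	PM2_supp	-	VUS	P
p.Gly3076Arg	3076	Gly	Arg	1.03	1.21	PS3	-	-	-	-	-	-	-	N/O	N/O
p.Gly3076Val	3076	Gly	Val	1.16	1.30	PS3	PM1	PM5	-	-	inc	PM2_supp	-	LP	P
p.His2623Arg	2623	His	Arg	0.83	0.92	PS3	PM1	-	PP1	-	PP3	PM2_supp	-	LP	P
p.His2623Tyr	2623	His	Tyr	1.15	1.35	PS3	-	PM5	-	-	inc	PM2_supp	-	VUS	LP
p.Ile2627Phe	2627	Ile	Phe	1.01	1.18	PS3	-	-	-	-	inc	PM2_supp	-	VUS	LP
p.Ile2627Asn	2627	Ile	Asn	1.16	1.32	PS3	-	PM5	-	-	inc	PM2_supp	-	VUS	LP
p.Ile2751Ser	2751	Ile	Ser	1.04	1.21	PS3	-	-	-	-	inc	PM2_supp	-	VUS	VUS
p.Lys2630Gln	2630	Lys	Gln	0.98	1.15	PS3	-	-	-	-	-	-	-	N/O	N/O
p.Lys2657Thr	2657	Lys	Thr	1.05	1.19	PS3	-	-	-	-	inc	PM2_supp	-	VUS	VUS
p.Leu2510Pro	2510	Leu	Pro	1.06	1.24	PS3	PM1_supp	-	-	PM3_st	PP3	PM2_supp	-	LP	P
p.Leu2604Pro	2604	Leu	Pro	0.98	1.14	PS3	PM1	-	-	-	PP3	PM2_supp	-	VUS	P
p.Leu2647Pro	2647	Leu	Pro	1.00	1.13	PS3	-	-	PP1_mod	-	PP3	PM2_supp	-	VUS	P
p.Leu2653Pro	2653	Leu	Pro	0.92	1.07	PS3	-	-	-	-	inc	PM2_supp	-	VUS	LP
p.Leu2656Pro	2656	Leu	Pro	1.12	1.31	PS3	-	-	-	-	-	-	-	N/O	N/O
p.Leu2686Pro	2686	Leu	Pro	0.86	0.97	PS3	PM1	-	-	PM3_st	inc	PM2_supp	-	LP	P
p.Leu2688Pro	2688	Leu	Pro	1.00	1.13	PS3	-	-	PP1_mod	-	PP3	PM2_supp	-	VUS	P
p.Leu2721His	2721	Leu	His	0.92	1.07	PS3	PM1	-	-	-	inc	PM2_supp	-	VUS	LP
p.Leu2753Pro	2753	Leu	Pro	1.01	1.11	PS3	-	-	-	-	BP4	PM2_supp	-	VUS	VUS
p.Leu2792Arg	2792	Leu	Arg	1.07	1.24	PS3	-	-	-	-	PP3	PM2_supp	-	VUS	LP
p.Leu3101Arg	3101	Leu	Arg	1.15	1.30	PS3	PM1	-	PP1	PM3_st	inc	PM2_supp	-	P	P
p.Leu3125Phe	3125	Leu	Phe	1.08	1.26	PS3	-	-	-	-	-	-	-	N/O	N/O
p.Leu3125His	3125	Leu	His	0.96	1.12	PS3	-	-	-	-	-	-	-	N/O	N/O
p.Leu3125Arg	3125	Leu	Arg	0.91	1.06	PS3	-	-	-	-	-	-	-	N/O	N/O
p.Leu3180Pro	3180	Leu	Pro	1.37	1.59	PS3	-	-	-	-	-	-	-	N/O	N/O
p.Asn2622Asp	2622	Asn	Asp	1.20	1.36	PS3	-	-	-	-	-	-	-	N/O	N/O
p.Asn2622Ser	2622	Asn	Ser	1.40	1.56	PS3	-	-	-	-	inc	BS1	0.020% AFR	VUS	VUS
p.Asn2781Ile	2781	Asn	Ile	1.02	1.15	PS3	PM1_supp	-	-	-	inc	PM2_supp	-	VUS	LP
p.Asn3124Ile	3124	Asn	Ile	0.99	1.11	PS3	PM1	-	-	-	inc	PM2_supp	-	VUS	P
p.Gln2561Pro	2561	Gln	Pro	1.13	1.26	PS3	-	-	-	-	-	-	-	N/O	N/O
p.Arg2625Ile	2625	Arg	Ile	1.17	1.37	PS3	-	-	-	-	-	-	-	N/O	N/O
p.Arg2784Trp	2784	Arg	Trp	1.35	1.57	PS3	PM1_supp	-	PP1	PM3	inc	-	-	VUS	P
p.Arg2824Thr	2824	Arg	Thr	1.36	1.58	PS3	-	-	-	-	-	-	-	N/O	N/O
p.Arg3052Leu	3052	Arg	Leu	1.04	1.21	PS3	-	PM5	-	-	inc	PM2_supp	-	VUS	LP
p.Arg3052Trp	3052	Arg	Trp	0.97	1.08	PS3	-	-	-	-	inc	-	-	VUS	P
p.Ser2691Tyr	2691	Ser	Tyr	1.37	1.60	PS3	-	-	-	-	-	-	-	N/O	N/O
p.Thr2722Ala	2722	Thr	Ala	1.39	1.62	PS3	-	-	-	-	inc	PM2_supp	-	VUS	VUS
p.Thr2722Ile	2722	Thr	Ile	1.24	1.44	PS3	-	-	-	-	inc	PM2_supp	-	VUS	VUS
p.Thr2722Lys	2722	Thr	Lys	1.00	1.16	PS3	PM1	PM5	-	-	inc	PM2_supp	-	LP	P
p.Thr2722Arg	2722	Thr	Arg	1.08	1.26	PS3	PM1	-	-	-	inc	PM2_supp	-	VUS	P
p.Val2652Gly	2652	Val	Gly	1.14	1.33	PS3	-	-	-	-	-	-	-	N/O	N/O
p.Val2687Phe	2687	Val	Phe	1.14	1.29	PS3	PM1	-	-	-	inc	PM2_supp	-	VUS	LP
p.Trp2619Cys	2619	Trp	Cys	1.00	1.14	PS3	-	-	-	-	PP3	PM2_supp	-	VUS	LP
p.Trp2619Gly	2619	Trp	Gly	1.04	1.18	PS3	PM1	-	-	-	PP3	PM2_supp	-	VUS	P
p.Trp2619Ser	2619	Trp	Ser	0.97	1.13	PS3	-	-	-	-	-	-	-	N/O	N/O
p.Trp2626Arg	2626	Trp	Arg	1.09	1.23	PS3	PM1	-	-	-	PP3	PM2_supp	-	VUS	P
p.Trp2725Leu	2725	Trp	Leu	1.35	1.58	PS3	-	-	-	-	-	-	-	N/O	N/O
p.Trp2788Arg	2788	Trp	Arg	1.05	1.23	PS3	PM1_supp	-	-	-	inc	PM2_supp	-	VUS	LP
p.Trp2788Ser	2788	Trp	Ser	1.09	1.21	PS3	-	PM5	-	-	inc	PM2_supp	-	VUS	LP
p.Tyr2624Cys	2624	Tyr	Cys	1.51	1.64	PS3	PM1_supp	-	-	-	PP3	PM2_supp	-	VUS	LP
p.Tyr2624His	2624	Tyr	His	1.02	1.19	PS3	-	-	-	-	-	-	-	N/O	N/O
p.Tyr2660Asp	2660	Tyr	Asp	1.17	1.30	PS3	-	-	-	-	-	-	-	N/O	N/O
p.Tyr2726Cys	2726	Tyr	Cys	1.36	1.54	PS3	PM1	-	-	-	PP3	PM2_supp	-	VUS	P
p.Tyr3006Asp	3006	Tyr	Asp	1.06	1.18	PS3	-	-	-	-	inc	PM2_supp	-	VUS	VUS
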