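cytokine	gene	ensembl_id	chr	start	end	n_pqtl	r2_pqtl	n_eqtl	r2_eqtl
activePAI	SERPINE1	ENSG00000106366	7	100770370	100782547	1	0.003
bNGF	NGF	ENSG00000134259	1	115828537	115880857			1	0.002
CTACK	CCL27	ENSG00000213927	9	34661893	34662689	3	0.060	2	0.041
Eotaxin	CCL11	ENSG00000172156	17	32612687	32615199	6	0.015	4	0.010
FGFBasic	FGF2	ENSG00000138685	4	123747863	123819390			2	0.002
GROa	CXCL1	ENSG00000163739	4	74735109	74737019	11	0.272	1	0.127
HGF	HGF	ENSG00000019991	7	81331444	81399452	6	0.010
IL-16	IL16	ENSG00000172349	15	81517640	81605104	8	0.037	6	0.031
IL-18	IL18	ENSG00000150782	11	112013974	112034840	5	0.051	2	0.024
IL-1a	IL1A	ENSG00000115008	2	113531492	113542971			3	0.003
IL-1ra	IL1RN	ENSG00000136689	2	113885138	113891593	18	0.075	2	0.017
IL-2ra	IL2RA	ENSG00000134460	10	6052657	6104333	14	0.260	4	0.130
IL-6	IL6	ENSG00000136244	7	22766766	22771621	1	0.002	1	0.001
IL-7	IL7	ENSG00000104432	8	79645007	79717758	1	0.005
IL-8	CXCL8	ENSG00000169429	4	74606223	74609433	1	0.004	2	0.005
IL-12p70	IL12A	ENSG00000168811	3	159706623	159713806	1	0.002
IL-12p70	IL12B	ENSG00000113302	5	158741791	158757481	1	0.002
IP-10	CXCL10	ENSG00000169245	4	76942269	76944689	5	0.020
MCP-1	CCL2	ENSG00000108691	17	32582296	32584220	8	0.006	3	0.001
MCP-3	CCL7	ENSG00000108688	17	32597235	32599261	13	0.289
MCSF	CSF1	ENSG00000184371	1	110453233	110473616	13	0.049	3	0.018
MIF	MIF	ENSG00000240972	22	24236565	24237409	2	0.019	2	0.020
MIG	CXCL9	ENSG00000138755	4	76922623	76928641	1	0.011	2	0.008
MIP1a	CCL3	ENSG00000277632	17	34415603	34417506	34	0.217	1	0.059
MIP1b	CCL4	ENSG00000275302	17	34431220	34433014	26	0.147	3	0.003
PDGFbb	PDGFB	ENSG00000100311	22	39619685	39640957	1	0.001
RANTES	CCL5	ENSG00000271503	17	34198496	34207377	1	0.009	1	0.009
SCF	KITLG	ENSG00000049130	12	88886570	88974250	3	0.006	2	0.001
SCGFb	CLEC11A	ENSG00000105472	19	51226605	51228981	2	0.016	1	0.004
SeSelectin	SELE	ENSG00000007908	1	169691781	169703220	2	0.008	2	0.002
sICAM	ICAM1	ENSG00000090339	19	10381517	10397291	25	0.168	2	0.004
sVCAM	VCAM1	ENSG00000162692	1	101185196	101204601	1	0.003	1	0.003
TNF-A	TNF	ENSG00000232810	6	31543344	31546112	2	0.004
TNF-B	LTA	ENSG00000226979	6	31539876	31542100			1	0.001
TRAIL	TNFSF10	ENSG00000121858	3	172223298	172241297	46	0.027	5	0.006
VEGF	VEGFA	ENSG00000112715	6	43737946	43754223	21	0.073	1	0.0004
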