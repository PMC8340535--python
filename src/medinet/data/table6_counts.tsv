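sample	rna_down	rna_not	rna_up	protein_down	protein_not	protein_up	phosphosite_down	phosphosite_not	phosphosite_up	mirna_down	mirna_not	mirna_up
Mouse1-N1	1621	18953	2158	867	2029	1651	413	8508	993	7	1243	51
Mouse1-N2	2269	18208	2651	979	2111	1328	407	1803	170	160	1212	59
Mouse1-N3	1785	18786	2394	681	2117	1155	314	8086	19	55	1234	42
Mouse2-N1	1909	18674	2473	1249	2568	1407	283	3354	284	6	1234	51
Mouse2-N2	1692	19053	2310	774	1786	1653	887	11258	15	54	1235	42
Mouse2-N3	1950	18843	2559	860	2269	1310	251	11311	2994	9	1225	57
Mouse3-N1	2005	18645	2404	627	2959	715	294	10211	255	49	1240	42
Mouse3-N2	2211	18392	2609	1228	2151	1933	286	4115	14	59	1218	54
Mouse3-N3	1862	18803	2326	986	2028	1849	15	8505	1019	51	1228	52
Mouse4-N1	1919	18640	2532	950	2128	1256	323	17591	239	53	1210	68
Mouse4-N2	1538	19196	2275	840	2019	1588	300	18111	461	62	1197	72
Mouse4-N3	2034	18319	2689	1070	2096	1715	454	13451	185	70	1196	65
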