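# Published closest heavy-atom distances (Å) between reciprocal-coupling
# residue pairs of Pak2, PKA and Src, measured on the crystal structures
# 1YHV (active Pak1, used as the Pak2 model), 1ATP (PKA) and 2SRC (Src).
# One row per (kinase, pair); pair_no numbers the equivalence classes.
protein	pair_no	class	pos_a	pos_b	distance_A
pak2	1	common	294	367	10.1
pak2	2	common	373	386	3.6
pak2	3	common	427	439	14.8
pak2	4	common	413	488	2.6
pak2	5	specific	481	497	10.1
pak2	6	specific	360	370	11.8
pak2	7	specific	380	461	25.3
pak2	8	specific	324	383	3.2
pak2	9	specific	409	480	8.8
pka	1	common	91	165	10.2
pka	2	common	171	184	3.1
pka	3	common	222	234	14.8
pka	4	common	208	280	2.8
pka	5	specific	273	294	10.1
pka	6	specific	158	168	12.4
pka	7	specific	178	258	22.5
pka	10	specific	229	238	7.4
src	1	common	310	385	9.6
src	2	common	391	404	2.9
src	3	common	446	459	15.0
src	4	common	432	506	2.7
src	8	specific	339	401	2.7
src	9	specific	428	498	8.6
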