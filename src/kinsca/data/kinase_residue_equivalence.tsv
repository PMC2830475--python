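# Curated catalytic-domain residue correspondences between human Pak2, PKA
# (catalytic subunit) and Src, from the structure-guided alignment of the three
# kinases.  One row per shared alignment position; blank cells mean no curated
# equivalent is recorded for that kinase.  Partial by construction: it covers
# the residues that appear in conservation and coupling reports.
pak2	pka	src
294	91	310
323	120
324	121	339
340	153
360	158
367	165	385
370	168
373	171	391
380	178
383		401
386	184	404
387	185
402	197	416
404	199
405	200
409		428
413	208	432
427	222	446
434	229
439	234	459
461	258
480		498
481	273
488	280	506
497	294
	238
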