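# Published per-gene directions reported by two external CR meta-analyses for genes overlapping the rat multi-tissue CR study's top commonly regulated genes. 'absent' = gene not reported by that meta-analysis.
gene_symbol	function	study_direction	ref1	ref2
Nampt	NAD metabolism	up	absent	up
Glul	glutamate metabolism	up	absent	up
Sult1a1	xenobiotic metabolism	up	up	up
Fmo1	xenobiotic metabolism	up	absent	up
Dbp	circadian rhythm	up	up	down
Cmtm6	immune system	down	absent	down
Hsp90aa1	chaperone protein	down	absent	down
Actg1	structural protein	down	down	down
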