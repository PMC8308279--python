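# Published per-condition direction entries (U=up, D=down, .=not informative) for the 20 most commonly regulated probe sets across the 36 CR conditions of the rat multi-tissue CR study (GEO GSE18297 / GSE176300).
probe_set_id	gene_symbol	direction	reported_count	liver_1w_5	liver_1w_10	liver_1w_20	liver_1w_30	liver_1m_5	liver_1m_10	liver_1m_20	liver_1m_30	adipose_1w_5	adipose_1w_10	adipose_1w_20	adipose_1w_30	adipose_1m_5	adipose_1m_10	adipose_1m_20	adipose_1m_30	muscle_1w_5	muscle_1w_10	muscle_1w_20	muscle_1w_30	muscle_1m_5	muscle_1m_10	muscle_1m_20	muscle_1m_30	brain_1w_5	brain_1w_10	brain_1w_20	brain_1w_30	brain_1m_5	brain_1m_10	brain_1m_20	brain_1m_30	intestine_1m_5	intestine_1m_10	intestine_1m_20	intestine_1m_30
1390430_at	Nr1d2	up	29	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	.	U	U	U	U	U	U	U	U	.	.	.	.	U	U	.	.	U	U	U	U
1370708_a_at	Akr1c14	up	21	.	U	U	U	U	U	U	U	U	U	U	U	.	U	U	U	U	U	.	.	.	U	.	U	.	.	.	.	.	.	.	.	U	.	U	U
1389014_at	Nampt	up	21	.	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	.	.	U	U	.	U	.	.	.	.	.	.	.	.	.	.	U	U	.	U
1367633_at	Glul	up	20	.	U	U	U	U	.	.	.	U	U	U	U	U	U	U	U	.	U	U	U	U	U	U	U	.	.	.	.	.	.	.	.	.	U	.	.
1370019_at	Sult1a1	up	20	.	.	.	.	.	.	.	.	.	U	U	U	.	.	U	U	U	U	U	U	U	U	U	U	.	.	.	.	U	U	.	U	U	U	U	U
1386870_at	Glul	up	20	.	U	U	U	U	.	.	U	U	U	U	U	U	U	U	U	.	.	U	U	U	U	U	U	.	.	.	.	.	.	.	.	.	U	.	.
1386901_at	Cd36	up	20	.	U	U	U	.	.	.	.	U	U	U	U	.	.	U	.	U	U	U	U	U	U	U	U	.	.	.	.	.	.	.	.	U	U	U	U
1387053_at	Fmo1	up	20	U	U	U	U	U	U	U	U	.	.	U	U	.	.	U	U	U	U	U	U	U	U	U	U	.	.	.	.	.	.	.	.	.	.	.	.
1387669_a_at	Ephx1	up	20	.	.	.	.	.	.	.	.	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	.	.	.	.	.	.	.	.	U	U	U	U
1387874_at	Dbp	up	20	.	.	.	.	.	.	.	.	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	.	.	.	.	.	.	.	.	U	U	U	U
1372056_at	Cmtm6	down	25	D	D	D	D	D	D	D	D	.	D	D	D	D	D	D	D	D	D	D	D	D	D	D	D	D	.	D	.	.	.	.	.	.	.	.	.
1367979_s_at	Cyp51	down	23	D	D	D	D	D	D	D	D	.	.	.	.	.	D	D	D	D	D	D	D	D	.	D	D	D	D	D	D	.	.	.	.	.	D	.	.
1388850_at	Hsp90aa1	down	21	.	.	.	.	.	.	.	.	.	D	D	D	D	D	D	D	D	D	D	D	D	D	D	D	D	D	D	D	.	.	.	.	.	D	D	.
1371327_a_at	Actg1	down	20	D	D	D	D	D	D	D	D	.	.	D	D	.	D	D	D	.	D	D	D	D	D	D	D	.	.	.	.	.	.	.	.	.	.	.	.
1367857_at	Fads1	down	19	.	.	D	D	.	.	.	D	.	D	D	D	D	D	D	D	D	D	D	D	D	D	D	D	.	.	.	.	.	.	.	.	.	.	D	.
1371390_at	Tubb4b	down	19	D	D	D	D	D	D	D	D	.	.	D	D	D	D	D	D	.	.	D	.	D	D	D	D	.	.	.	.	.	.	.	.	.	.	.	.
1371653_at	Tpm4	down	19	.	.	D	D	D	D	.	.	.	.	D	D	.	D	D	D	.	.	D	D	D	D	D	D	D	D	D	D	.	.	.	.	.	.	.	.
1371840_at	S1pr1	down	19	.	D	D	D	D	D	D	.	.	D	.	D	.	D	D	D	.	.	.	.	D	D	D	D	D	D	D	D	.	.	.	.	.	.	.	.
1372727_at		down	19	D	D	D	D	D	D	D	D	D	D	.	.	.	D	.	.	D	D	D	D	D	D	D	D	.	.	.	.	.	.	.	.	.	.	.	.
1373718_at	Tubb2a	down	19	D	D	D	D	D	D	D	D	D	D	D	D	D	D	D	D	.	.	.	.	D	D	.	D	.	.	.	.	.	.	.	.	.	.	.	.
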