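# Published change values (log2 vs control) for the top five up-regulated probe sets per tissue in the rat multi-tissue CR study (GEO GSE18297 / GSE176300). '.' = condition not assayed.
tissue	probe_set_id	gene_symbol	slr_1w_5	slr_1w_10	slr_1w_20	slr_1w_30	slr_1m_5	slr_1m_10	slr_1m_20	slr_1m_30
liver	1388271_at	Mt2A	2.2	3.5	4.5	4.5	2.3	2.9	3.4	4.0
liver	1371237_a_at	Mt1a///Ttr	2.4	3.6	4.1	4.0	2.9	3.4	3.5	3.9
liver	1387336_at	Nat8	1.0	2.4	3.7	3.7	2.0	2.6	3.2	3.5
liver	1387156_at	Hsd17b2	3.9	4.4	4.4	4.1	3.9	4.1	3.8	3.3
liver	1368213_at	Por	0.8	1.5	2.5	3.1	1.5	2.0	2.5	2.8
adipose	1387874_at	Dbp	2.5	2.7	2.9	2.9	2.8	2.9	3.0	2.5
adipose	1388039_a_at	Gabbr1	1.0	1.7	2.0	2.4	1.6	2.3	2.3	2.4
adipose	1368406_at	Star	1.2	1.6	2.3	2.4	1.4	1.7	2.2	2.3
adipose	1372536_at	Adck3	0.8	1.2	1.9	2.3	0.9	1.4	1.9	2.2
adipose	1387174_a_at	Star	1.0	1.5	1.9	2.0	1.5	1.8	2.2	2.2
muscle	1378927_at		0.8	1.0	1.6	1.6	1.4	1.5	1.8	1.8
muscle	1387053_at	Fmo1	0.6	1.0	0.9	1.5	0.9	0.9	1.1	1.6
muscle	1368971_a_at	Synj2	0.7	0.8	1.0	1.1	1.2	1.1	1.3	1.5
muscle	1369150_at	Pdk4	0.3	0.9	0.6	1.2	0.7	0.6	0.8	1.4
muscle	1370019_at	Sult1a1	0.7	0.9	1.2	1.4	1.0	1.1	1.2	1.4
intestine	1370019_at	Sult1a1	.	.	.	.	1.2	1.3	1.3	1.8
intestine	1371076_at	Cyp2b1///Cyp2b2	.	.	.	.	1.3	1.1	2.0	1.8
intestine	1368303_at	Per2	.	.	.	.	1.3	1.3	1.6	1.4
intestine	1367774_at	Gsta1///LOC102550391	.	.	.	.	0.5	1.0	0.7	1.3
intestine	1369455_at	Abcg5	.	.	.	.	1.3	0.9	1.9	1.2
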