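# Published change values (log2 vs control) for the top five down-regulated probe sets per tissue in the rat multi-tissue CR study (GEO GSE18297 / GSE176300). '.' = condition not assayed.
tissue	probe_set_id	gene_symbol	slr_1w_5	slr_1w_10	slr_1w_20	slr_1w_30	slr_1m_5	slr_1m_10	slr_1m_20	slr_1m_30
liver	1367707_at	Fasn	-1.55	-2.45	-4.3	-4.4	-1.7	-2.85	-3.6	-4.4
liver	1367708_a_at	Fasn	-1.2	-2.15	-4	-4.3	-1.6	-2.75	-3.5	-3.9
liver	1373718_at	Tubb2a	-1.6	-2.9	-3.75	-4.05	-2.55	-3.15	-3.45	-3.4
liver	1370870_at	Me1	-1.5	-1.9	-2.95	-2.95	-1.75	-2.25	-2.55	-2.85
liver	1367854_at	Acly	-1.1	-1.85	-2.55	-2.8	-1.4	-2	-2.3	-2.55
adipose	1367998_at	Slpi	-1.15	-1.4	-1.35	-2.85	-0.7	-2.5	-2.45	-1.95
adipose	1368294_at	Dnase1l3	-1.1	-0.5	-1.4	-2.3	-0.9	-1.45	-1.8	-1.8
adipose	1389006_at	Mpeg1	-0.75	-0.7	-1.2	-2	-0.7	-1.2	-1.6	-1.6
adipose	1368189_at	Dhcr7	-0.9	-0.65	-1.45	-1.7	-0.9	-0.85	-1.3	-1.4
adipose	1373718_at	Tubb2a	-0.45	-0.8	-0.8	-0.95	-0.75	-0.95	-0.8	-1.15
muscle	1388395_at	G0s2	-0.7	-1.7	-2.5	-2.9	-2.5	-3.5	-3	-2.2
muscle	1378423_at	Nmrk2	-0.3	-0.9	-1.3	-1.6	-1.8	-1.7	-1.8	-2.1
muscle	1379416_at	LOC100362819	-1.1	-1.4	-2	-2.2	-1.8	-1.5	-2.5	-2
muscle	1378586_at	Cish	-2.5	-2.2	-2.2	-2.2	-2	-1.7	-0.6	-1.9
muscle	1374204_at	Wsb1	-1.4	-1.1	-1.8	-1.9	-2.5	-2.6	-2.5	-1.4
brain	1375043_at		-2.3	-2.4	-2	-2.1	-1.3	-1.4	-1.2	-1.4
brain	1369067_at	Nr4a3	-1	-1	-0.9	-1.1	-0.9	-1.2	-1.2	-1.1
brain	1368321_at	Egr1	-0.7	-0.7	-0.4	-0.7	-1.2	-1.4	-1.2	-0.9
intestine	1369717_at	Nmu	.	.	.	.	-1	-1.1	-1.1	-1.7
intestine	1387758_at	Akp3	.	.	.	.	-0.5	-1	-0.2	-1.7
intestine	1378658_at	Clca4	.	.	.	.	-0.9	-1.6	-1	-1.4
intestine	1368247_at	Hspa1a///Hspa1b	.	.	.	.	-1.4	-1.1	-1.1	-1.2
intestine	1389986_at		.	.	.	.	-0.7	-0.5	-1.1	-1.1
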