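layer	transcript_id	log2_ratio	probability	symbol
sense	101109197	-10.5912106	0.886583566	NT5C3L
sense	101116281	-7.40151954	0.969520529	LOC101116281
sense	101120858	-4.57602606	0.868500902	LOC101120858
sense	443313	-4.45466762	0.848327046	Small proline-rich
sense	101109718	-4.16402747	0.835055492	CA4
sense	101108013	-4.13509115	0.838991854	AQP8
sense	101118004	-3.99924015	0.86634137	LOC101118004
sense	101115395	-3.90149163	0.829820677	PGLYRP1
sense	101114011	-3.8813167	0.855789733	LOC101114011
sense	101107368	-3.8266707	0.827278443	SLC25A35
sense	101104026	-3.72227757	0.855311355	S100A8
sense	101115563	-3.4495271	0.829328632	ABCC11
sense	101109387	-3.38125687	0.87068777	GLYATL2
sense	101106121	-3.3527916	0.870715106	LOC101106121
sense	101115336	-3.29504885	0.839237877	DNASE1L2
sense	101116409	-3.16407151	0.86568531	LOC101116409
sense	101113168	-3.1562348	0.826690722	LOC101113168
sense	100137068	-2.97890634	0.857115521	LOC100137068
sense	101116799	-2.80442661	0.859794434	LOC101116799
sense	NM_001009395.1	-2.67922661	0.847588978	-
sense	101102714	-2.61084761	0.822795364	LOC101102714
sense	101102540	-2.3882578	0.861489257	RPL39
sense	101102697	-2.14152458	0.81083593	DNAJC12
sense	101108654	-2.10679611	0.847930676	LOC101108654
sense	101116537	-1.89220493	0.803933629	LOC101116537
sense	101121216	-1.86897593	0.842094473	LOC101121216
sense	101112716	-1.85095925	0.834194413	KRT7
sense	101121307	-1.5666126	0.800489312	ACSM3
sense	101111121	-1.46170294	0.809141108	CD82
sense	101114256	-1.40678444	0.802238806	ACTG2
sense	101109430	-1.32738037	0.80115904	KRT1
sense	101105583	1.377957974	0.802293478	GSDMA
sense	101110063	1.491887466	0.816426111	HSPA2
sense	100135694	1.587840025	0.830968782	RPS27A
sense	443218	1.679295263	0.826485703	FOS
sense	101113964	1.819875496	0.838185446	PDCD6IP
sense	101119862	2.058276167	0.826212345	LIPK
sense	101120443	2.31282643	0.827415122	LOC101120443
sense	101105188	4.991770667	0.839825597	DAP
sense	100144758	6.03994716	0.834235416	CCNA2
antisense	101116281	-9.15903036	0.941608145	Bos d2
antisense	443313	-7.587465008	0.819808271	SPRR
antisense	101108013	-7.807354922	0.844108795	AQP8
antisense	101120353	-5.685396543	0.88975588	major allergen I polypeptide chain 2-like
antisense	101120550	-6.896227669	0.975067811	SMC1A
antisense	101113086	-9.556506055	0.957344034	primary amine oxidase
antisense	101113693	-8.661778098	0.914297923	ABP
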