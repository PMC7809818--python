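# Annotation of the Cobitis macrostigma mitogenome (GenBank MT259034, 16,636 bp)
# name	type	start	end	strand	anticodon
trnF	tRNA	1	69	H	GAA
rrnS	rRNA	70	1021	H
trnV	tRNA	1022	1093	H	TAC
rrnL	rRNA	1094	2768	H
trnL1	tRNA	2769	2843	H	TAA
nd1	PCG	2845	3819	H
trnI	tRNA	3826	3897	H	GAT
trnQ	tRNA	3896	3966	L	TTG
trnM	tRNA	3968	4036	H	CAT
nd2	PCG	4037	5081	H
trnW	tRNA	5082	5151	H	TCA
trnA	tRNA	5153	5221	L	TGC
trnN	tRNA	5223	5295	L	GTT
OL	OL	5296	5325	H
trnC	tRNA	5326	5391	L	GCA
trnY	tRNA	5392	5460	L	GTA
cox1	PCG	5462	7012	H
trnS2	tRNA	7014	7084	L	TGA
trnD	tRNA	7087	7158	H	GTC
cox2	PCG	7172	7906	H
trnK	tRNA	7933	8008	H	TTT
atp8	PCG	8010	8177	H
atp6	PCG	8168	8851	H
cox3	PCG	8851	9634	H
trnG	tRNA	9635	9706	H	TCC
nd3	PCG	9707	10055	H
trnR	tRNA	10056	10125	H	TCG
nd4l	PCG	10126	10422	H
nd4	PCG	10416	11797	H
trnH	tRNA	11798	11866	H	GTG
trnS1	tRNA	11867	11934	H	GCT
trnL2	tRNA	11936	12008	H	TAG
nd5	PCG	12009	13847	H
nd6	PCG	13844	14365	L
trnE	tRNA	14366	14434	L	TTC
cytb	PCG	14441	15581	H
trnT	tRNA	15582	15653	H	TGT
trnP	tRNA	15652	15721	L	TGG
CR	CR	15720	16636	H
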