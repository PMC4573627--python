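index	mirna_id	mirna_name	mirna_coords	strand	tss_coords	score	qvalue	category
1	MI0000989	ath-MIR171b	chr1:3961348-3961464	-	3961764-3961864	NA	NA	independent
2	MI0005386	ath-MIR830	chr1:4820355-4820549	-	4820549-4820649	NA	NA	independent
3	MI0000218	ath-MIR159b	chr1:6220646-6220841	+	6220446-6220546	NA	NA	independent
4	MI0001005	ath-MIR394a	chr1:7058194-7058310	+	7055994-7056094	NA	NA	independent
5	MI0019201	ath-MIR5630a	chr1:12011152-12011223	-	12011523-12011623	NA	NA	independent
6	MI0019211	ath-MIR5630b	chr1:12023526-12023597	-	12023997-12024097	NA	NA	independent
7	MI0000193	ath-MIR161	chr1:17825685-17825857	+	17825485-17825585	NA	NA	independent
8	MI0019208	ath-MIR5636	chr1:18549959-18550036	+	18549659-18549759	NA	NA	independent
9	MI0001078	ath-MIR406	chr1:19430078-19430277	-	19431177-19431277	NA	NA	independent
10	MI0019235	ath-MIR5652	chr1:23412989-23413436	-	23413636-23413736	NA	NA	independent
11	MI0000196	ath-MIR163	chr1:24884066-24884396	+	24883966-24884066	NA	NA	independent
12	MI0001425	ath-MIR414	chr1:25137456-25137563	-	25137763-25137863	NA	NA	independent
13	MI0000189	ath-MIR159a	chr1:27713233-27713416	-	27713616-27713716	NA	NA	independent
14	MI0015817	ath-MIR4228	chr1:28889375-28889532	+	28889175-28889275	NA	NA	independent
15	MI0005105	ath-MIR775	chr1:29422452-29422574	+	29422052-29422152	NA	NA	independent
16	MI0001013	ath-MIR396a	chr2:4142323-4142473	-	4142673-4142773	NA	NA	independent
17	MI0005109	ath-MIR779	chr2:9560761-9560923	+	9560161-9560261	NA	NA	independent
18	MI0020189	ath-MIR5995b	chr2:10026910-10027050	+	10026310-10026410	NA	NA	independent
19	MI0020188	ath-MIR5595a	chr2:10026910-10027050	-	10027050-10027150	NA	NA	independent
20	MI0000178	ath-MIR156a	chr2:10676451-10676573	-	10676673-10676773	NA	NA	independent
21	MI0000215	ath-MIR172a	chr2:11942914-11943015	-	11943215-11943315	NA	NA	independent
22	MI0017889	ath-MIR5021	chr2:11974711-11974881	-	11975181-11975281	NA	NA	independent
23	MI0000201	ath-MIR166a	chr2:19176108-19176277	+	19176008-19176108	NA	NA	independent
24	MI0001072	ath-MIR403	chr2:19415052-19415186	+	19414952-19415052	NA	NA	independent
25	MI0000208	ath-MIR167a	chr3:8108072-8108209	+	8107972-8108072	NA	NA	independent
26	MI0005383	ath-MIR827	chr3:22122760-22122936	-	22123036-22123136	NA	NA	independent
27	MI0000202	ath-MIR166b	chr3:22922206-22922325	+	22921906-22922006	NA	NA	independent
28	MI0002407	ath-MIR447a	chr4:1528134-1528370	-	1529270-1529370	NA	NA	independent
29	MI0017896	ath-MIR5026	chr4:7844496-7844688	+	7842896-7842996	NA	NA	independent
30	MI0005405	ath-MIR850	chr4:7845707-7845927	+	7842907-7843007	NA	NA	independent
31	MI0005440	ath-MIR863	chr4:7846597-7846899	+	7842897-7842997	NA	NA	independent
32	MI0015815	ath-MIR4221	chr4:8460516-8460662	+	8459516-8459616	NA	NA	independent
33	MI0000210	ath-MIR168a	chr4:10578635-10578772	+	10578335-10578435	NA	NA	independent
34	MI0000180	ath-MIR156c	chr4:15415418-15415521	-	15415821-15415921	NA	NA	independent
35	MI0019242	ath-MIR5658	chr4:18485438-18485531	-	18486431-18486531	NA	NA	independent
36	MI0000198	ath-MIR164b	chr5:287584-287736	+	287484-287584	NA	NA	independent
37	MI0000216	ath-MIR172b	chr5:1188207-1188301	-	1188501-1188601	NA	NA	independent
38	MI0000195	ath-MIR162b	chr5:7740598-7740708	-	7740908-7741008	NA	NA	independent
39	MI0019216	ath-MIR5643a	chr5:11667797-11667879	+	11667197-11667297	NA	NA	independent
40	MI0001014	ath-MIR396b	chr5:13611798-13611932	+	13611698-13611798	NA	NA	independent
41	MI0000211	ath-MIR168b	chr5:18358788-18358911	-	18359011-18359111	NA	NA	independent
42	MI0001075	ath-MIR405b	chr5:20632514-20632637	+	20630514-20630614	NA	NA	independent
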