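element	host	integration_location	att_length	state	access	reference
pT26-2	Themococcus sp. 26-2	1-21,566	51	Free/integrated	295126597	Soler et al. (2010)
TKV2	Thermococcus kodakarensis KOD1	320,075-347,187	48/53	Integrated	AP006878.1	Keller et al. (2016)
TKV3	Thermococcus kodakarensis KOD1	499,284-526,865	48/53	Integrated	AP006878.1	Fukui et al. (2005)
TguDSM11113_IP1	Thermococcus guayamensis DSM11113	153,065-178,766	46	Integrated	CPU007140.1	This analysis
TliDSM5473_IP1	Thermococcus litoralis DSM 5473	500,722-523,246	44	Integrated	CP006670.1	This analysis
TbaCH5_IP1	Thermococcus barophilus CH5	770,185-788,746	44	Integrated	CP013050.1	This analysis
TbaCH5_IP2	Thermococcus barophilus CH5	2,013,643-2,038,136	48	Integrated	CP013050.1	This analysis
TspJCM11816_IP1	Thermococcus sp. JCM11816	162,578-186,018	49	Integrated	Ga0128353_102	This analysis
TGV1	Thermococcus gammatolerans EJ3	621,669-642,462	50	Integrated	CP001398.1	Keller et al. (2016)
TceDSM17994_IP1	Thermococcus celericrescens DSM17994	15,770-43,341	129	Integrated	NZ_LLYW01000013	This analysis
PchGC74_IP1	Pyrococcus chitonophagus GC74	1,137,169-1,159,084	46	Integrated	NZ_CP015193	This analysis
PkuNCB100_IP1	Pyrorcoccus kukulkanii sp. NCB100	456,321-486,708	102	Integrated	CP010835.1	This analysis
PHV1	Pyrococcus horikoshii OT3	1,061,525-1,083,228	47	Integrated	BA000001.2	Keller et al. (2016)
PyaCH1_IP16	Pyrococcus yayanosii CH1	1,238,312-1,255,830	46	Integrated	CP002779	This analysis
PspNA2_IP1	Pyrococcus sp. NA2	1,199,678-1,221,811	47	Integrated	CP002670	This analysis
pGE2 = PabGE2_IP1	Pyrococcus abyssi GE2	1,467,989-1,488,841	48	Free/integrated	-	This analysis
MMC6V1	Methanococcus maripaludis C6	358-48,565	56	Integrated	NC_009975	Keller et al. (2016)
MMC7V1	Methanococcus maripaludis C7*	No detectable limits	-	Integrated	NC_009637	Keller et al. (2016)
MMC7V2	Methanococcus maripaludis C7	1,436,513-1,469,347	56	Integrated	NC_009637	Keller et al. (2016)
MMPV1 = MmaS2_IP	Methanococcus maripaludis S2	735,195-773,477	53	Integrated	NC_005791	Keller et al. (2016)
MmaKA1_IP1	Methanococcus maripaludis KA1	466,296-491,741	54	Integrated	AP011526	This analysis
MmaOS7_IP1	Methanococcus maripaludis OS7	45,126-475,878	54	Integrated	AP011528	This analysis
MmaC5_IP1	Methanococcus maripaludis C5*	No detectable limits	-	Remnant		This analysis
MmaX1_IP1	Methanococcus maripaludis X1	No detectable limits	-	Integrated	340623184	This analysis
MVV1	Methanococcus voltae A3	1,715,487-1,742,050	102	Integrated	NC_014222	Keller et al. (2016)
MthDSM2095_IP1	Methanothermococcus thermolithotrophicus DSM2095	1-21,165	54	-	NZ_AQXV01000029	This analysis
MigKol5_IP1	Methanotorris igneus Kol5	500,181-524,602	58	Integrated	NC_015562	This analysis
MspFS406-22_IP1	Methanocaldococcus sp. FS406-22	1,092,561-1,123,012	54	Integrated	NC_013887	This analysis
pMEFER01	Methanocaldococcus fervens AG86	1-22,190	57	Free	NC_013157	Soler et al. (2010)
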