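name	relative_core_size	replication	ori_rep	integrase_type	target_trna
PspNA2_IP1	7	MCM	1	Type I	tRNA-Val
TbaCH5_IP1	3	-	Not found	Type I	tRNA-Val
TceDSMA7994_IP1	6	T26-22p like	1	Type I	tRNA-Thr
PchCG74_IP1	7	-	1	Type I	tRNA-Gly
PHV1	8	-	1	Type I	tRNA-Ala
PyaCH1_IP16	9	-	1	Type I	tRNA-Gly
TbaCH5_IP2	9	MCM	1	Type I	tRNA-Tyr
PabGE2_IP2	7	T26-22p like	1	Type I	tRNA-Ala
PkuNCB100_IP1	7	-	1	Type I	tRNA-Ala
TliDSM5473_IP1	8	-	Not found	Type I	tRNA-Gly
pT26-2	8	T26-22p like	1	Type I	tRNA-Arg
TguDSM11113_IP1	9	-	1	Type I	tRNA-Arg
TGV1	9	-	1	Type I	tRNA-Arg
TKV3	8	T26-22p like	1	Type I	tRNA-Arg
TKV2	8	-	1	Type I	tRNA-Glu
TspJCM11816_IP1	7	-	1	Type I	tRNA-Arg
MmaOS7_IP1	9	MCM like	1	Type II	tRNA-Ser
MmaKA1_IP1	8	MCM like	2	Type II	tRNA-Ser
MmaX1_IP1	9	MCM	Not found	Type II	-
MMC7V1	7	MCM	Not found	Type II	tRNA-Ser
MmaS2_IP	8	MCM	1	Type II	tRNA-Ser
MMC6V1	9	MCM	1	Type II	tRNA-Ser
MMC7V2	8	MCM like	1	Type II	tRNA-Ser
MmaC5_IP1	2	-	Not found	-	-
MVV1	7	-	2	Type II	tRNA-Leu
MthDSM2095_IP1	8	MCM like	1	Type II	tRNA-Ser
pMEFER01	9	MCM	1	Type II	-
MspFS406-22_IP1	8	-	1	Type II	tRNA-Ser
MigKol5_IP1	8	-	1	Type II	tRNA-Ser
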