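id	accession	domain	aa_start	aa_end	nt_length
BatPyV4a	NC_038556.1	DnaJ	12	67	168
BatPyV4a	NC_038556.1	helicase	405	564	480
ApanPyV1	NC_019853.1	DnaJ	12	77	198
ApanPyV1	NC_019853.1	helicase	441	601	483
BatPyV5b-1	NC_026767.1	DnaJ	12	74	189
BatPyV5b-1	NC_026767.1	helicase	376	536	483
BatPyV5a	NC_026768.1	DnaJ	12	67	168
BatPyV5a	NC_026768.1	helicase	382	546	495
OraPyV-Bor	NC_013439.1	DnaJ	12	77	198
OraPyV-Bor	NC_013439.1	helicase	422	602	543
CardiodermaPyV	NC_020067.1	DnaJ	12	77	198
CardiodermaPyV	NC_020067.1	helicase	556	716	483
BatPyV4b	NC_028120.1	helicase	458	651	582
ChPyV	NC_014743.1	DnaJ	12	96	255
ChPyV	NC_014743.1	helicase	379	580	606
VmPyV1	NC_019844.1	DnaJ	12	80	207
VmPyV1	NC_019844.1	helicase	479	640	486
VmPyV3	NC_025898.1	DnaJ	12	75	192
VmPyV3	NC_025898.1	helicase	462	622	483
EidolonPyV	NC_020068.1	helicase	588	752	495
GgorgPyV1	NC_025380.1	helicase	554	714	483
HPyV9	NC_015150.1	DnaJ	12	86	225
HPyV9	NC_015150.1	helicase	446	606	483
HPyV12	NC_020890.1	helicase	473	635	489
MfasPyV1	NC_019851.1	DnaJ	12	86	225
MfasPyV1	NC_019851.1	helicase	465	665	603
MCPyV	NC_010277.2	helicase	567	727	483
HaPyV	NC_001663.2	helicase	522	682	483
BatPyV3b	NC_028123.1	helicase	467	630	492
MPyV	NC_001515.2	helicase	549	709	483
NJPyV	NC_024118.1	DnaJ	12	80	207
NJPyV	NC_024118.1	helicase	476	636	483
OtomopsPyV	NC_020066.1	DnaJ	12	92	243
OtomopsPyV	NC_020066.1	helicase	483	643	483
OtomopsPyV1	NC_020071.1	helicase	520	680	483
PtrovPyV2a	NC_025370.1	helicase	556	716	483
PtrovPyV3	NC_019855.1	DnaJ	12	75	192
PtrovPyV3	NC_019855.1	helicase	486	646	483
PtrovPyV4	NC_019856.1	DnaJ	12	75	192
PtrovPyV4	NC_019856.1	helicase	489	646	474
PtrovPyV5	NC_019857.1	DnaJ	12	86	225
PtrovPyV5	NC_019857.1	helicase	439	599	483
PtrosPyV2	NC_019858.1	DnaJ	12	85	222
PtrosPyV2	NC_019858.1	helicase	432	632	603
PtrovPyV1a	NC_025368.1	helicase	558	718	483
PbadPyV2	NC_039051.1	DnaJ	12	92	243
PbadPyV2	NC_039051.1	helicase	476	637	486
PrufPyV1	NC_019850.1	DnaJ	12	93	246
PrufPyV1	NC_019850.1	helicase	476	637	486
RacPyV	NC_023845.1	helicase	504	685	546
RnorPyV1	NC_027531.1	helicase	535	698	492
BatPyV3a-B0454	NC_038557.1	helicase	477	637	483
OraPyV-Sum	NC_028127.1	DnaJ	12	75	192
OraPyV-Sum	NC_028127.1	helicase	489	649	483
TSPyV	NC_014361.1	DnaJ	12	77	198
TSPyV	NC_014361.1	helicase	445	605	483
YbPyV1	NC_025894.1	DnaJ	12	75	192
YbPyV1	NC_025894.1	helicase	463	663	603
AelPyV1	NC_022519.1	helicase	400	564	495
BatPyV2c	NC_038558.1	helicase	559	719	483
BVPyV	NC_028117.1	DnaJ	12	67	168
BVPyV	NC_028117.1	helicase	383	574	576
BatPyV6a	NC_026762.1	helicase	395	557	489
BatPyV6b	NC_026770.1	helicase	407	570	492
BatPyV6c	NC_026769.1	helicase	426	587	486
SLPyV	NC_013796.1	DnaJ	12	77	198
SLPyV	NC_013796.1	helicase	397	556	480
CalbPyV1	NC_019854.2	helicase	410	570	483
CeryPyV1	NC_025892.1	DnaJ	12	75	192
CeryPyV1	NC_025892.1	helicase	402	562	483
VmPyV2	NC_025896.1	DnaJ	12	75	192
VmPyV2	NC_025896.1	helicase	402	562	483
CVPyV	NC_028119.1	DnaJ	12	67	168
CVPyV	NC_028119.1	helicase	382	573	576
BatPyV2a	NC_028122.1	DnaJ	12	80	207
BatPyV2a	NC_028122.1	helicase	406	565	480
EPyV	NC_017982.1	DnaJ	12	86	225
EPyV	NC_017982.1	helicase	402	562	483
BKPyV	NC_001538.1	DnaJ	12	75	192
BKPyV	NC_001538.1	helicase	402	562	483
KIPyV	NC_009238.1	helicase	410	572	489
JCPyV	NC_001699.1	DnaJ	12	75	192
JCPyV	NC_001699.1	helicase	401	561	483
WsPyV	NC_032120.1	DnaJ	12	77	198
WsPyV	NC_032120.1	helicase	400	561	486
SV40	NC_001669.1	DnaJ	12	75	192
SV40	NC_001669.1	helicase	400	560	483
MasPyV	NC_025895.1	helicase	414	576	489
MmelPyV1	NC_026473.1	DnaJ	12	80	207
MmelPyV1	NC_026473.1	helicase	365	559	585
MiniopterusPyV	NC_020069.1	DnaJ	12	75	192
MiniopterusPyV	NC_020069.1	helicase	369	560	576
MPtV	NC_001505.2	helicase	418	573	468
MyPyV	NC_011310.1	helicase	441	603	489
PtrovPyV8	NC_028635.1	DnaJ	12	75	192
PtrovPyV8	NC_028635.1	helicase	402	562	483
PteronotusPyV	NC_020070.1	DnaJ	12	80	207
PteronotusPyV	NC_020070.1	helicase	405	564	480
BatPyV2b	NC_028121.1	DnaJ	12	80	207
BatPyV2b	NC_028121.1	helicase	406	617	636
RatPyV2	NC_032005.1	DnaJ	12	79	204
RatPyV2	NC_032005.1	helicase	474	634	483
SsciPyV1	NC_038559.1	helicase	410	572	489
SquiPyV	NC_009951.1	helicase	411	570	480
AlPyV	NC_034251.1	DnaJ	12	67	168
AlPyV	NC_034251.1	helicase	407	567	483
WUPyV	NC_009539.1	DnaJ	12	89	234
WUPyV	NC_009539.1	helicase	417	579	489
YbPyV2	AB767295.2	DnaJ	12	75	192
YbPyV2	AB767295.2	helicase	402	562	483
HPyV6	NC_014406.1	helicase	393	571	537
HPyV7	NC_014407.1	helicase	416	576	483
MWPyV	NC_018102.1	helicase	421	580	480
STLPyV	NC_020106.1	DnaJ	12	83	216
STLPyV	NC_020106.1	helicase	406	566	483
ADPyV	NC_026141.2	DnaJ	8	61	162
ADPyV	NC_026141.2	helicase	408	582	525
BFDV	NC_004764.2	DnaJ	6	82	231
BFDV	NC_004764.2	helicase	372	532	483
ButcherbirdPyV	NC_023008.1	DnaJ	8	67	180
ButcherbirdPyV	NC_023008.1	helicase	410	572	489
CaPyV	NC_017085.1	DnaJ	8	61	162
CaPyV	NC_017085.1	helicase	390	550	483
CpyV	NC_007922.1	DnaJ	11	80	210
CpyV	NC_007922.1	helicase	405	569	495
EgouPyV1	NC_039052.1	DnaJ	8	75	204
EgouPyV1	NC_039052.1	helicase	374	572	597
FPyV	NC_007923.1	DnaJ	6	70	195
FPyV	NC_007923.1	helicase	382	543	486
GHPV	NC_004800.1	DnaJ	8	81	222
GHPV	NC_004800.1	helicase	404	599	588
HunFPyV	NC_039053.1	DnaJ	6	77	216
HunFPyV	NC_039053.1	helicase	382	543	486
BassPyV1	NC_025790.1	helicase	338	495	474
BPyV	NC_001442.1	DnaJ	10	73	192
BPyV	NC_001442.1	helicase	391	586	588
DPyV	NC_025899.1	DnaJ	11	77	201
DPyV	NC_025899.1	helicase	357	536	540
GfPyV1	NC_026244.1	helicase	348	517	510
SspPyV	NC_026944.1	helicase	372	529	474
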