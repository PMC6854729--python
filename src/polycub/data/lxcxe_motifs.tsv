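id	accession	aa_start	aa_end	peptide
BatPyV4a	NC_038556.1	107	111	LRCDE
ApanPyV1	NC_019853.1	122	126	LFCNE
OraPyV-Bor	NC_013439.1	122	126	LFCDE
CardiodermaPyV	NC_020067.1	212	216	LYCDE
BatPyV4b	NC_028120.1	152	156	LLCEE
VmPyV1	NC_019844.1	107	111	LHCNE
VmPyV3	NC_025898.1	131	135	LFCSE
EidolonPyV	NC_020068.1	236	240	LRCDE
GgorgPyV1	NC_025380.1	200	204	LFCDE
HPyV9	NC_015150.1	123	127	LFCSE
MfasPyV1	NC_019851.1	125	129	LFCTE
MCPyV	NC_010277.2	212	216	LFCDE
HaPyV	NC_001663.2	130	134	LTCQE
BatPyV3b	NC_028123.1	107	111	LYCDE
MPyV	NC_001515.2	142	146	LFCYE
NJPyV	NC_024118.1	107	111	LHCDE
OtomopsPyV	NC_020066.1	107	111	LYCDE
OtomopsPyV1	NC_020071.1	185	189	LRCDE
PtrovPyV2a	NC_025370.1	200	204	LFCDE
PtrovPyV5	NC_019857.1	123	127	LFCSE
PtrosPyV2	NC_019858.1	108	112	LYCSE
PtrovPyV1a	NC_025368.1	203	207	LYCDE
PbadPyV2	NC_039051.1	107	111	LHCNE
PrufPyV1	NC_019850.1	107	111	LHCNE
RacPyV	NC_023845.1	167	171	LFCEE
RnorPyV1	NC_027531.1	128	132	LYCSE
BatPyV3a-B0454	NC_038557.1	107	111	LHCHE
TSPyV	NC_014361.1	122	126	LFCHE
YbPyV1	NC_025894.1	131	135	LFCSE
BatPyV2c	NC_038558.1	223	227	LLCEE
BVPyV	NC_028117.1	146	150	LTCHE
BatPyV6a	NC_026762.1	84	88	LFCHE
BatPyV6b	NC_026770.1	98	102	LFCHE
BatPyV6c	NC_026769.1	100	104	LFCRE
SLPyV	NC_013796.1	113	117	LHCHE
CalbPyV1	NC_019854.2	100	104	LFCNE
CeryPyV1	NC_025892.1	105	109	LFCHE
VmPyV2	NC_025896.1	105	109	LFCHE
CVPyV	NC_028119.1	145	149	LSCNE
EPyV	NC_017982.1	105	109	LRCDE
BKPyV	NC_001538.1	105	109	LFCHE
KIPyV	NC_009238.1	108	112	LRCNE
JCPyV	NC_001699.1	105	109	LFCHE
WsPyV	NC_032120.1	113	117	LHCNE
SV40	NC_001669.1	103	107	LFCSE
MasPyV	NC_025895.1	101	105	LFCNE
MmelPyV1	NC_026473.1	111	115	LRCDE
MiniopterusPyV	NC_020069.1	103	107	LHCHE
MPtV	NC_001505.2	103	107	LFCNE
PtrovPyV8	NC_028635.1	105	109	LFCHE
PteronotusPyV	NC_020070.1	108	112	LRCDE
BatPyV2b	NC_028121.1	108	112	LRCDE
RatPyV2	NC_032005.1	178	182	LHCDE
SsciPyV1	NC_038559.1	101	105	LFCHE
SquiPyV	NC_009951.1	101	105	LFCHE
AlPyV	NC_034251.1	107	111	LYCNE
WUPyV	NC_009539.1	108	112	LRCNE
YbPyV2	AB767295.2	105	109	LFCHE
HPyV6	NC_014406.1	109	113	LYCDE
HPyV7	NC_014407.1	109	113	LYCTE
MWPyV	NC_018102.1	105	109	LSCNE
STLPyV	NC_020106.1	105	109	LTCNE
ADPyV	NC_026141.2	69	73	LYCEE
ButcherbirdPyV	NC_023008.1	70	74	LFCDE
CaPyV	NC_017085.1	67	71	LSCNE
CpyV	NC_007922.1	69	73	LQCEE
EgouPyV1	NC_039052.1	70	74	LYCEE
FPyV	NC_007923.1	60	64	LFCDE
GHPV	NC_004800.1	65	69	LFCDE
HunFPyV	NC_039053.1	60	64	LFCDE
BassPyV1	NC_025790.1	105	109	LMCGE
BPyV	NC_001442.1	93	97	LHCDE
DPyV	NC_025899.1	82	86	LYCDE
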