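id	accession	group
BatPyV4a	NC_038556.1	M
ApanPyV1	NC_019853.1	P
BatPyV5b-1	NC_026767.1	M
BatPyV5a	NC_026768.1	M
OraPyV-Bor	NC_013439.1	P
CardiodermaPyV	NC_020067.1	M
BatPyV4b	NC_028120.1	M
ChPyV	NC_014743.1	P
VmPyV1	NC_019844.1	P
VmPyV3	NC_025898.1	P
EidolonPyV	NC_020068.1	M
GgorgPyV1	NC_025380.1	P
HPyV9	NC_015150.1	H
HPyV12	NC_020890.1	H
MfasPyV1	NC_019851.1	P
MCPyV	NC_010277.2	H
HaPyV	NC_001663.2	M
BatPyV3b	NC_028123.1	M
MPyV	NC_001515.2	M
NJPyV	NC_024118.1	H
OtomopsPyV	NC_020066.1	M
OtomopsPyV1	NC_020071.1	M
PtrovPyV2a	NC_025370.1	P
PtrovPyV3	NC_019855.1	P
PtrovPyV4	NC_019856.1	P
PtrovPyV5	NC_019857.1	P
PtrosPyV2	NC_019858.1	P
PtrovPyV1a	NC_025368.1	P
PbadPyV2	NC_039051.1	P
PrufPyV1	NC_019850.1	P
RacPyV	NC_023845.1	M
RnorPyV1	NC_027531.1	M
BatPyV3a-B0454	NC_038557.1	M
OraPyV-Sum	NC_028127.1	P
TSPyV	NC_014361.1	H
YbPyV1	NC_025894.1	P
AelPyV1	NC_022519.1	M
BatPyV2c	NC_038558.1	M
BVPyV	NC_028117.1	M
BatPyV6a	NC_026762.1	M
BatPyV6b	NC_026770.1	M
BatPyV6c	NC_026769.1	M
SLPyV	NC_013796.1	M
CalbPyV1	NC_019854.2	P
CeryPyV1	NC_025892.1	P
VmPyV2	NC_025896.1	P
CVPyV	NC_028119.1	M
BatPyV2a	NC_028122.1	M
EPyV	NC_017982.1	M
BKPyV	NC_001538.1	H
KIPyV	NC_009238.1	H
JCPyV	NC_001699.1	H
WsPyV	NC_032120.1	M
SV40	NC_001669.1	P
MasPyV	NC_025895.1	M
MmelPyV1	NC_026473.1	M
MiniopterusPyV	NC_020069.1	M
MPtV	NC_001505.2	M
MyPyV	NC_011310.1	M
PtrovPyV8	NC_028635.1	P
PteronotusPyV	NC_020070.1	M
BatPyV2b	NC_028121.1	M
RatPyV2	NC_032005.1	M
SsciPyV1	NC_038559.1	P
SquiPyV	NC_009951.1	P
AlPyV	NC_034251.1	M
WUPyV	NC_009539.1	H
YbPyV2	AB767295.2	P
HPyV6	NC_014406.1	H
HPyV7	NC_014407.1	H
MWPyV	NC_018102.1	H
STLPyV	NC_020106.1	H
ADPyV	NC_026141.2	A
BFDV	NC_004764.2	A
ButcherbirdPyV	NC_023008.1	A
CaPyV	NC_017085.1	A
CpyV	NC_007922.1	A
EgouPyV1	NC_039052.1	A
FPyV	NC_007923.1	A
GHPV	NC_004800.1	A
HunFPyV	NC_039053.1	A
BassPyV1	NC_025790.1	F
BPyV	NC_001442.1	M
DPyV	NC_025899.1	M
GfPyV1	NC_026244.1	F
SspPyV	NC_026944.1	F
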