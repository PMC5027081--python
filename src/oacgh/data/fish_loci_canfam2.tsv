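locus	gene	bac_clone	chrom	start	end
BCL11B	BCL11B	326-K01	8	70661395	70752579
IGH	IGH	027-N17	8	75997304	76191846
VEGFA	VEGFA	152-L05	12	15212673	15228610
CCNC	CCNC	268-D08	12	60739913	60764849
FOXO3A	FOXO3A	048-I05	12	68583078	68701688
CDKN2A	CDKN2A	325-C12	11	44255629	44256009
MYC	MYC	335-M01	13	28238008	28242545
KIT	KIT	98-B16	13	50017518	50212194
CDK6	CDK6	181-D14	14	21147772	21367160
EZH2	EZH2	300-P18	16	4905169	4971032
MYCBP2	MYCBP2	216-G13	22	33561172	33820510
FLT3	FLT3	062-D23	25	14581755	14658045
PTEN	PTEN	521-G14	26	40921802	40981821
HEY1	HEY1	484-E08	29	30184049	30186972
E2F5	E2F5	157-A19	29	34748851	34758529
NFKB2	NFKB2	001-D14	28	17903193	17910910
ERG	ERG	100-F17	31	35578420	35760306
MLLT2	MLLT2	468-E14	32	13354180	13586952
CD83	CD83	127-B24	35	16354899	16533175
DEK	DEK	517-A02	35	20035294	20172093
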