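# Synthetic stand-in for the published inborn-errors-of-immunity gene panel
# (485 human symbols). The symbols are genuine immunodeficiency/immune genes
# compiled from domain knowledge, but the exact membership differs from the
# published classification table, which is not redistributed here.
# Empty mouse_symbol = resolve via the case convention / curated exceptions.
human_symbol	mouse_symbol
IL2RG	
JAK3	
IL7R	
PTPRC	
CD3D	
CD3E	
CD247	
CORO1A	
LAT	
RAG1	
RAG2	
DCLRE1C	
PRKDC	
NHEJ1	
LIG4	
XRCC4	
ADA	
AK2	
RAC2	
CD40	
CD40LG	
ICOS	
ICOSLG	
IL21	
IL21R	
CD8A	
ZAP70	
LCK	
ITK	
MALT1	
CARD11	
BCL10	
BCL11B	
IKZF1	
IKZF2	
IKZF3	
POLD1	
POLD2	
RELA	
RELB	
REL	
NFKB1	
NFKB2	
NFKBIA	
NFKBIB	
IKBKB	
IKBKG	
MAP3K14	
CHUK	
TBX1	
FOXN1	
CHD7	
SEMA3E	
PNP	
CD3G	
PAX1	
TAP1	
TAP2	
TAPBP	
B2M	
CIITA	
RFX5	
RFXANK	
RFXAP	
DOCK2	
DOCK8	
DOCK11	
STK4	
RHOH	
MST1	
WAS	
WIPF1	
ARPC1B	
WDR1	
MRTFA	
RASGRP1	
CARMIL2	
ITGB2	
ATM	
NBN	
MRE11	
RAD50	
BLM	
DNMT3B	
ZBTB24	
CDCA7	
HELLS	
PMS2	
MLH1	
MSH2	
MSH6	
ERCC6L2	
GINS1	
MCM4	
POLE	
POLE2	
RNF168	
STAT3	
IL6R	
IL6ST	
ZNF341	
ERBB2IP	
TGFBR1	
TGFBR2	
CARD14	
PGM3	
SPINK5	
COMMD1	
DKC1	
TERT	
TINF2	
RTEL1	
NHP2	
NOP10	
PARN	
ACD	
STN1	
CTC1	
STIM1	
ORAI1	
MAGT1	
CD27	
CD70	
CTPS1	
SH2D1A	
XIAP	
TNFRSF9	
TNFRSF4	
IL2RA	
IL2RB	
STAT5B	
FOXP3	
CTLA4	
LRBA	
DEF6	
BACH2	
AIRE	
ITCH	
JAK1	
STAT1	
STAT2	
IRF2BP2	
BTK	
IGHM	
IGLL1	
CD79A	
CD79B	
BLNK	
PIK3CD	
PIK3R1	
PIK3CG	
PTEN	
TCF3	
SLC39A7	
TOP2B	
FNIP1	
ARHGEF1	
SEC61A1	
MOGS	
TRNT1	
AICDA	
UNG	
INO80	
CD19	
CD81	
CR2	
MS4A1	
TNFRSF13B	
TNFRSF13C	
TNFSF12	
TNFSF13	
ATP6AP1	
CTNNBL1	
KMT2D	
KDM6A	
PRF1	
UNC13D	
STX11	
STXBP2	
RAB27A	
LYST	
AP3B1	
AP3D1	
NLRC4	
CDC42	
SLC7A7	
HAVCR2	
ZNFX1	
FAS	
FASLG	
CASP8	
CASP10	
FADD	
KRAS	
NRAS	
MEFV	
MVK	
NLRP3	
NLRP1	
NLRP12	
NOD2	
PSTPIP1	
IL1RN	
IL36RN	
ADA2	
TNFRSF1A	
STING1	
IFIH1	
DDX58	
ADAR	
RNASEH2A	
RNASEH2B	
RNASEH2C	
SAMHD1	
TREX1	
ISG15	
USP18	
ACP5	
PSMB8	
PSMB9	
PSMB4	
PSMG2	
POMP	
OTULIN	
RBCK1	
RNF31	
TNFAIP3	
ALPK1	
NCKAP1L	
COPA	
ELANE	
HAX1	
G6PC3	
VPS45	
JAGN1	
GFI1	
CSF3R	
CXCR4	
CXCR2	
SBDS	
EFL1	
DNAJC21	
SRP54	
TAFAZZIN	
CLPB	
USB1	
CEBPE	
SMARCD2	
VPS13B	
LAMTOR2	
CYBA	
CYBB	
NCF1	
NCF2	
NCF4	
CYBC1	
G6PD	
MPO	
SLC35C1	
FERMT3	
CTSC	
FPR1	
GATA2	
CSF2RA	
CSF2RB	
IFNGR1	
IFNGR2	
IL12B	
IL12RB1	
IL12RB2	
IL23R	
TYK2	
SPPL2A	
IRF8	
RORC	
TBX21	
MYD88	
IRAK4	
IRAK1	
TLR3	
TICAM1	
TBK1	
UNC93B1	
TRAF3	
IRF3	
IRF7	
IRF9	
IFNAR1	
IFNAR2	
DBR1	
POLR3A	
POLR3C	
POLR3F	
CARD9	
IL17F	
IL17RA	
IL17RC	
TRAF3IP2	
STAT4	
C1QA	
C1QB	
C1QC	
C1R	
C1S	
C2	
C3	
C4A	
C4B	
C5	
C6	
C7	
C8A	
C8B	
C8G	
C9	
MASP1	
MASP2	
FCN3	
CFB	
CFD	
CFP	
CFH	
CFI	
CFHR1	
CFHR5	
CD46	
CD55	
CD59	
SERPING1	
THBD	
FANCA	
FANCB	
FANCC	
BRCA2	
FANCD2	
FANCE	
FANCF	
FANCG	
FANCI	
FANCL	
FANCM	
BRIP1	
PALB2	
RAD51	
RAD51C	
SLX4	
ERCC4	
UBE2T	
MAD2L2	
RFWD3	
GATA1	
RPS19	
RPL5	
RPL11	
RPS26	
SP110	
TTC7A	
TTC37	
SKIV2L	
IL10	
IL10RA	
IL10RB	
RIPK1	
TGFB1	
PRKCD	
TMC6	
TMC8	
CIB1	
SAMD9	
SAMD9L	
SRP72	
MPEG1	
TET2	
SOCS1	
IFNG	
TNF	
IL6	
CCL2	
EPG5	
PEPD	
PLCG2	
APOL1	
NFAT5	
TFRC	
CCBE1	
FAT4	
KIAA0825	
HYOU1	
EXTL3	
SMARCAL1	
NSMCE3	
RNF113A	
MTHFD1	
TCN2	
SLC46A1	
DHFR	
MSN	
CD28	
IL9R	
TPP2	
KMT2A	
SETD2	
KAT6A	
DNMT1	
UBA1	
SLC37A4	
G6PC1	
TCIRG1	
SNX10	
OSTM1	
PLEKHM1	
TNFSF11	
TNFRSF11A	
CSF1R	
CTSK	
IKZF4	
ZEB2	
SOCS4	
SH3BP2	
CA2	
CLCN7	
PYCR1	
ALDOA	
TKT	
ALG13	
ATP6V0A2	
EXOC2	
COG4	
COG6	
VPS33B	
VIPAS39	
STX3	
UNC45A	
MYO5B	
EPCAM	
NEUROG3	
WNT2B	
DIAPH1	
ACTB	
ACTG1	
ARPC2	
ARPC5	
WASF2	
NCKIPSD	
CORO1C	
RAC3	
DOCK5	
ITGA4	
SELL	
SELPLG	
CEBPA	
SPI1	
RUNX1	
MECOM	
ERG	
ETV6	
ANKRD26	
SRP9	
RPL35A	
RPS24	
RPS17	
RPS10	
RPL26	
RPS7	
TSR2	
CD3EAP	
TRAC	
TRBC1	
PTCRA	
CD5	
CD6	
CD2	
CD58	
SLAMF1	
SH2B3	
PTPN2	
PTPN22	
SOCS3	
CISH	
IL4R	
IL13	
IL5RA	
CRLF2	
TSLP	
IL7	
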