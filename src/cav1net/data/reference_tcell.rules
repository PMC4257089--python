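# cav1_cd4_tcell_reference v1.0
input APC
input ECM
input CGC
input Alpha_13L
input GalphaS_L
input GP130
input IFNB
input IFNG
input IFNGR1
input IFNGR2
input IL10
input IL10RA
input IL10RB
input IL12
input IL15
input IL15RA
input IL18
input IL21
input IL22
input IL23
input IL27
input IL27RA
input IL2
input IL2RB
input IL4
input IL6
input IL6RA
input IL9
input TGFB
input GalphaQ_L
input Galpha12_13_L
input CAV1_Activator
TCR = APC
CD28 = APC & CGC
CAV1 = TCR | ECM | CAV1_Activator
LCK = TCR & CAV1
FYN = TCR & CAV1
TCRzeta = LCK | FYN
ZAP70 = TCRzeta
LAT = ZAP70
Integrin = ECM & CAV1
IL2R = IL2
IL10R = IL10 & IL10RA & IL10RB
IFNGR = IFNG & IFNGR1 & IFNGR2
IL6R = IL6 & IL6RA & GP130
IL27R = IL27 & IL27RA & GP130
IL15R = IL15 & IL15RA & IL2RB
SHC1 = Integrin | IL2R
GRB2 = SHC1 | LAT
SOS = GRB2
RAS = SOS
KSR1 = CAV1
RAF = RAS & KSR1
MEK = RAF
ERK = MEK
MAPK = ERK & (Integrin | IL2R)
CARMA1 = LCK
BCL10 = CARMA1 | !CAV1
MALT1 = CARMA1 & BCL10
NFKB = MALT1
CD26 = !CAV1
SHP2 = Integrin
NOS2A = NFKB & !IL10R
PI3K = CD28 | GalphaQ_L
AKT = PI3K
RAC1 = Integrin | !CAV1
Cdc42 = Galpha12_13_L | Alpha_13L
ARP2_3 = RAC1 | Cdc42
F_actin = ARP2_3 & Integrin
Th1_Signal = IFNGR | IL12 & IL18 | IL27R | IFNB
GATA3 = !CAV1 & !Th1_Signal
Gamma_Chain = IL2R | IL15R | IL4 | IL9 | IL21
STAT3_Signal = IL6R | IL10R | IL21 | IL22 | IL23
Treg_Skew = TGFB & !Th1_Signal
cAMP_PKA = GalphaS_L
Survival = AKT | Gamma_Chain | STAT3_Signal
Proliferation = ERK & NFKB & !Treg_Skew & !cAMP_PKA
Cytoskeletal_Rearrangement = F_actin
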