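source	target	sign	note
APC	TCR	activation	TCR engagement by peptide-MHC on an antigen-presenting cell
APC	CD28	activation	CD28 costimulation by APC ligands; signals independently of CAV1
CGC	CD28	activation	CD28 costimulation by APC ligands; signals independently of CAV1
TCR	CAV1	activation	membrane scaffold engaged by TCR and integrin/ECM contact; the activator species drives it independently of upstream regulators
ECM	CAV1	activation	membrane scaffold engaged by TCR and integrin/ECM contact; the activator species drives it independently of upstream regulators
CAV1_Activator	CAV1	activation	membrane scaffold engaged by TCR and integrin/ECM contact; the activator species drives it independently of upstream regulators
TCR	LCK	activation	CAV1-dependent p56lck activation at the immune synapse
CAV1	LCK	activation	CAV1-dependent p56lck activation at the immune synapse
TCR	FYN	activation	CAV1-dependent Fyn activation at the immune synapse
CAV1	FYN	activation	CAV1-dependent Fyn activation at the immune synapse
LCK	TCRzeta	activation	TCR-zeta chain phosphorylation by the Src kinases Lck/Fyn
FYN	TCRzeta	activation	TCR-zeta chain phosphorylation by the Src kinases Lck/Fyn
TCRzeta	ZAP70	activation	ZAP70 recruitment to phosphorylated TCR-zeta
ZAP70	LAT	activation	LAT adaptor phosphorylation by ZAP70
ECM	Integrin	activation	integrin engagement of extracellular-matrix components, scaffolded by CAV1
CAV1	Integrin	activation	integrin engagement of extracellular-matrix components, scaffolded by CAV1
IL2	IL2R	activation	IL-2 receptor engagement
IL10	IL10R	activation	IL-10 receptor complex (ligand plus R-alpha and R-beta chains)
IL10RA	IL10R	activation	IL-10 receptor complex (ligand plus R-alpha and R-beta chains)
IL10RB	IL10R	activation	IL-10 receptor complex (ligand plus R-alpha and R-beta chains)
IFNG	IFNGR	activation	IFN-gamma receptor complex (ligand plus R1 and R2 chains)
IFNGR1	IFNGR	activation	IFN-gamma receptor complex (ligand plus R1 and R2 chains)
IFNGR2	IFNGR	activation	IFN-gamma receptor complex (ligand plus R1 and R2 chains)
IL6	IL6R	activation	IL-6 receptor complex; requires the gp130 co-receptor
IL6RA	IL6R	activation	IL-6 receptor complex; requires the gp130 co-receptor
GP130	IL6R	activation	IL-6 receptor complex; requires the gp130 co-receptor
IL27	IL27R	activation	IL-27 receptor complex; requires the gp130 co-receptor
IL27RA	IL27R	activation	IL-27 receptor complex; requires the gp130 co-receptor
GP130	IL27R	activation	IL-27 receptor complex; requires the gp130 co-receptor
IL15	IL15R	activation	IL-15 receptor complex; shares the IL-2R beta chain
IL15RA	IL15R	activation	IL-15 receptor complex; shares the IL-2R beta chain
IL2RB	IL15R	activation	IL-15 receptor complex; shares the IL-2R beta chain
Integrin	SHC1	activation	SHC adaptor recruited by integrin and IL-2R signaling
IL2R	SHC1	activation	SHC adaptor recruited by integrin and IL-2R signaling
SHC1	GRB2	activation	GRB2 adaptor recruited via SHC1 or LAT
LAT	GRB2	activation	GRB2 adaptor recruited via SHC1 or LAT
GRB2	SOS	activation	SOS exchange factor in the GRB2 complex
SOS	RAS	activation	RAS activation by SOS
CAV1	KSR1	activation	KSR1 scaffold of the RAF/MEK/ERK cascade, organized by CAV1
RAS	RAF	activation	RAF activation by RAS on the KSR1 scaffold
KSR1	RAF	activation	RAF activation by RAS on the KSR1 scaffold
RAF	MEK	activation	MEK activation by RAF
MEK	ERK	activation	ERK activation by MEK
ERK	MAPK	activation	MAPK-pathway readout: ERK output under sustained receptor engagement (integrin or IL-2R)
Integrin	MAPK	activation	MAPK-pathway readout: ERK output under sustained receptor engagement (integrin or IL-2R)
IL2R	MAPK	activation	MAPK-pathway readout: ERK output under sustained receptor engagement (integrin or IL-2R)
LCK	CARMA1	activation	CARMA1 activation downstream of TCR-proximal kinase signaling
CARMA1	BCL10	activation	BCL10, engaged by CARMA1 and restrained by CAV1 (up in knockout)
CAV1	BCL10	inhibition	BCL10, engaged by CARMA1 and restrained by CAV1 (up in knockout)
CARMA1	MALT1	activation	MALT1 in the CARMA1-BCL10-MALT1 complex
BCL10	MALT1	activation	MALT1 in the CARMA1-BCL10-MALT1 complex
MALT1	NFKB	activation	NF-kB activation by the CBM complex
CAV1	CD26	inhibition	CD26, sequestered by its interaction with CAV1 (up in knockout)
Integrin	SHP2	activation	SHP2 phosphatase recruited to integrin adhesion signaling
NFKB	NOS2A	activation	inducible NO synthase: NF-kB-driven, suppressed by IL-10
IL10R	NOS2A	inhibition	inducible NO synthase: NF-kB-driven, suppressed by IL-10
CD28	PI3K	activation	PI3-kinase activation via CD28 costimulation or GalphaQ GPCR
GalphaQ_L	PI3K	activation	PI3-kinase activation via CD28 costimulation or GalphaQ GPCR
PI3K	AKT	activation	AKT activation by PI3K
Integrin	RAC1	activation	RAC1 GTPase: integrin-driven, restrained by CAV1 (up in knockout)
CAV1	RAC1	inhibition	RAC1 GTPase: integrin-driven, restrained by CAV1 (up in knockout)
Galpha12_13_L	Cdc42	activation	Cdc42 GTPase activation by Galpha12/13-coupled receptor ligands
Alpha_13L	Cdc42	activation	Cdc42 GTPase activation by Galpha12/13-coupled receptor ligands
RAC1	ARP2_3	activation	ARP2/3 actin nucleation downstream of RAC1/Cdc42
Cdc42	ARP2_3	activation	ARP2/3 actin nucleation downstream of RAC1/Cdc42
ARP2_3	F_actin	activation	filamentous-actin polymerization at the integrin contact
Integrin	F_actin	activation	filamentous-actin polymerization at the integrin contact
IFNGR	Th1_Signal	activation	Th1-skewing cytokine input (IFN-gamma R, IL-12+IL-18, IL-27, type-I IFN)
IL12	Th1_Signal	activation	Th1-skewing cytokine input (IFN-gamma R, IL-12+IL-18, IL-27, type-I IFN)
IL18	Th1_Signal	activation	Th1-skewing cytokine input (IFN-gamma R, IL-12+IL-18, IL-27, type-I IFN)
IL27R	Th1_Signal	activation	Th1-skewing cytokine input (IFN-gamma R, IL-12+IL-18, IL-27, type-I IFN)
IFNB	Th1_Signal	activation	Th1-skewing cytokine input (IFN-gamma R, IL-12+IL-18, IL-27, type-I IFN)
CAV1	GATA3	inhibition	GATA3 Th2 program: restrained by CAV1 and by Th1 cytokines
Th1_Signal	GATA3	inhibition	GATA3 Th2 program: restrained by CAV1 and by Th1 cytokines
IL2R	Gamma_Chain	activation	common gamma-chain cytokine input (IL-2/4/9/15/21)
IL15R	Gamma_Chain	activation	common gamma-chain cytokine input (IL-2/4/9/15/21)
IL4	Gamma_Chain	activation	common gamma-chain cytokine input (IL-2/4/9/15/21)
IL9	Gamma_Chain	activation	common gamma-chain cytokine input (IL-2/4/9/15/21)
IL21	Gamma_Chain	activation	common gamma-chain cytokine input (IL-2/4/9/15/21)
IL6R	STAT3_Signal	activation	STAT3-activating cytokine input (IL-6/10/21/22/23)
IL10R	STAT3_Signal	activation	STAT3-activating cytokine input (IL-6/10/21/22/23)
IL21	STAT3_Signal	activation	STAT3-activating cytokine input (IL-6/10/21/22/23)
IL22	STAT3_Signal	activation	STAT3-activating cytokine input (IL-6/10/21/22/23)
IL23	STAT3_Signal	activation	STAT3-activating cytokine input (IL-6/10/21/22/23)
TGFB	Treg_Skew	activation	TGF-beta-driven regulatory skew in the absence of Th1 input
Th1_Signal	Treg_Skew	inhibition	TGF-beta-driven regulatory skew in the absence of Th1 input
GalphaS_L	cAMP_PKA	activation	GalphaS-coupled cAMP/PKA tone
AKT	Survival	activation	cell-survival endpoint (AKT or cytokine-driven)
Gamma_Chain	Survival	activation	cell-survival endpoint (AKT or cytokine-driven)
STAT3_Signal	Survival	activation	cell-survival endpoint (AKT or cytokine-driven)
ERK	Proliferation	activation	proliferation endpoint: ERK and NF-kB without suppressive tone
NFKB	Proliferation	activation	proliferation endpoint: ERK and NF-kB without suppressive tone
Treg_Skew	Proliferation	inhibition	proliferation endpoint: ERK and NF-kB without suppressive tone
cAMP_PKA	Proliferation	inhibition	proliferation endpoint: ERK and NF-kB without suppressive tone
F_actin	Cytoskeletal_Rearrangement	activation	cytoskeletal-rearrangement endpoint (immune-synapse actin remodeling)
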