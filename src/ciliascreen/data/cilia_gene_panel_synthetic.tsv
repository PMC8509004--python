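symbol	compartments
TUBA1A	axoneme
TUBA1C	axoneme
TUBA8	axoneme
TUBB	axoneme
TUBB2A	axoneme
TUBB2B	axoneme
TUBB3	axoneme
TUBB4A	axoneme
TUBB4B	axoneme
SPAG6	axoneme
SPAG16	axoneme
SPAG17	axoneme
HYDIN	axoneme
CFAP43	axoneme
CFAP44	axoneme
CFAP54	axoneme
RSPH1	axoneme
RSPH4A	axoneme
RSPH9	axoneme
DNAI1	axoneme
DNAI2	axoneme
PACRG	axoneme
CILSYN001	axoneme
CILSYN002	axoneme
CILSYN003	axoneme
CILSYN004	axoneme
CILSYN005	axoneme
CILSYN006	axoneme
CILSYN007	axoneme
CILSYN008	axoneme
CILSYN009	axoneme
CILSYN010	axoneme
CILSYN011	axoneme
CILSYN012	axoneme
CILSYN013	axoneme
CILSYN014	axoneme
CILSYN015	axoneme
SNAP25	basal body
TUBG1	basal body
TUBGCP2	basal body
TUBGCP3	basal body
TUBGCP4	basal body
TUBGCP5	basal body
TUBGCP6	basal body
CEP164	basal body
CEP290	basal body
CEP83	basal body
CEP89	basal body
OFD1	basal body
SDCCAG8	basal body
NPHP1	basal body
MKS1	basal body
B9D1	basal body
B9D2	basal body
TMEM67	basal body
POC1A	basal body
POC1B	basal body
PLK4	basal body
SASS6	basal body
STIL	basal body
CEP152	basal body
CEP192	basal body
CENPJ	basal body
ODF2	basal body
NIN	basal body
TTBK2	basal body
KIAA0586	basal body
RAB8A	basal body
RAB11A	basal body
EHD1	basal body
CCDC28B	basal body;centrosome
CILSYN016	basal body
CILSYN017	basal body
CILSYN018	basal body
CILSYN019	basal body
CILSYN020	basal body
CILSYN021	basal body
CILSYN022	basal body
CILSYN023	basal body
CILSYN024	basal body
CILSYN025	basal body
CILSYN026	basal body
CILSYN027	basal body
CILSYN028	basal body
CILSYN029	basal body
CILSYN030	basal body
CILSYN031	basal body
CILSYN032	basal body
CILSYN033	basal body
CILSYN034	basal body
CILSYN035	basal body
CILSYN036	basal body
CILSYN037	basal body
CILSYN038	basal body
CILSYN039	basal body
CILSYN040	basal body
CILSYN041	basal body
CILSYN042	basal body
CILSYN043	basal body
CILSYN044	basal body
CILSYN045	basal body
CILSYN046	basal body
CILSYN047	basal body
CILSYN048	basal body
CILSYN049	basal body
CILSYN050	basal body
CILSYN051	basal body
CILSYN052	basal body
CILSYN053	basal body
CILSYN054	basal body
CILSYN055	basal body
CILSYN056	basal body
CILSYN057	basal body
CILSYN058	basal body
CILSYN059	basal body
CILSYN060	basal body
CILSYN061	basal body
CILSYN062	basal body
CILSYN063	basal body
CILSYN064	basal body
CILSYN065	basal body
CILSYN066	basal body
CILSYN067	basal body
CILSYN068	basal body
CILSYN069	basal body
CILSYN070	basal body
CILSYN071	basal body
NPHP4	transition zone
RPGRIP1L	transition zone
TMEM216	transition zone
TMEM138	transition zone
TMEM231	transition zone
TMEM237	transition zone
AHI1	transition zone
CC2D2A	transition zone
TCTN1	transition zone
TCTN2	transition zone
TCTN3	transition zone
KIF17	kinesin
KIF3A	kinesin
KIF3B	kinesin
KIF3C	kinesin
KIFAP3	kinesin
KIF7	kinesin
DYNC2H1	dynein
DYNC2LI1	dynein
WDR34	dynein
WDR60	dynein
DNAH5	dynein
DNAH11	dynein
DNAL1	dynein
DNALI1	dynein
DYNLL1	dynein
DYNLT1	dynein
WDR19	IFT-A
IFT172	IFT-A
IFT140	IFT-A
IFT122	IFT-A
WDR35	IFT-A
TTC21B	IFT-A
IFT88	IFT-B
IFT80	IFT-B
IFT20	IFT-B
IFT27	IFT-B
IFT52	IFT-B
IFT57	IFT-B
IFT74	IFT-B
TTC30A	IFT-B
TTC30B	IFT-B
BBS1	BBSome
BBS2	BBSome
BBS4	BBSome
BBS5	BBSome
BBS7	BBSome
BBS9	BBSome
TTC8	BBSome
BBIP1	BBSome
ARL6	BBSome
LZTFL1	BBSome
TRIP11	Golgi
GOLGA2	Golgi
GOLGA3	Golgi
GORASP1	Golgi
GORASP2	Golgi
ARF4	Golgi
RAB6A	Golgi
USO1	Golgi
RABL2A	cytosol
RABL2B	cytosol
TULP3	cytosol
UNC119	cytosol
UNC119B	cytosol
ARL3	cytosol
CILSYN072	cytosol
CILSYN073	cytosol
CILSYN074	cytosol
CILSYN075	cytosol
CILSYN076	cytosol
CILSYN077	cytosol
CILSYN078	cytosol
CILSYN079	cytosol
CILSYN080	cytosol
CILSYN081	cytosol
CILSYN082	cytosol
CILSYN083	cytosol
CILSYN084	cytosol
CILSYN085	cytosol
CILSYN086	cytosol
CILSYN087	cytosol
CILSYN088	cytosol
CILSYN089	cytosol
CILSYN090	cytosol
CILSYN091	cytosol
CILSYN092	cytosol
CILSYN093	cytosol
CILSYN094	cytosol
CILSYN095	cytosol
CILSYN096	cytosol
CILSYN097	cytosol
CILSYN098	cytosol
CILSYN099	cytosol
CILSYN100	cytosol
CILSYN101	cytosol
CILSYN102	cytosol
CILSYN103	cytosol
CILSYN104	cytosol
CILSYN105	cytosol
RFX3	nucleus
RFX4	nucleus
FOXJ1	nucleus
GLI1	nucleus
GLI2	nucleus
GLI3	nucleus
SUFU	nucleus
CILSYN106	nucleus
CILSYN107	nucleus
CILSYN108	nucleus
CILSYN109	nucleus
CILSYN110	nucleus
CILSYN111	nucleus
CILSYN112	nucleus
CILSYN113	nucleus
CILSYN114	nucleus
CILSYN115	nucleus
CILSYN116	nucleus
CILSYN117	nucleus
CILSYN118	nucleus
CILSYN119	nucleus
CILSYN120	nucleus
CILSYN121	nucleus
CILSYN122	nucleus
CILSYN123	nucleus
CILSYN124	nucleus
CILSYN125	nucleus
CILSYN126	nucleus
CILSYN127	nucleus
CILSYN128	nucleus
ARL13B	ciliary membrane
INPP5E	ciliary membrane
PKD1	ciliary membrane
PKD2	ciliary membrane
PKHD1	ciliary membrane
TMEM107	ciliary membrane
EVC	ciliary membrane
EVC2	ciliary membrane
MCHR1	GPCR
MC4R	GPCR
GALR2	GPCR
GALR3	GPCR
DRD2	GPCR
DRD5	GPCR
KISS1R	GPCR
SMO	GPCR
SSTR3	GPCR
NPY2R	GPCR
NPY5R	GPCR
LPAR6	GPCR
NMUR1	GPCR
HTR6	GPCR
GPR88	GPCR
GPR161	GPCR
GPR83	GPCR
GPR19	GPCR
CELSR2	GPCR
PTGER4	GPCR
OPN4	GPCR
TAAR1	GPCR
ADRB2	GPCR
HTR7	GPCR
GPR21	GPCR
FIS1	mitochondria
MFN1	mitochondria
MFN2	mitochondria
OPA1	mitochondria
DNM1L	mitochondria
TOMM20	mitochondria
TIMM23	mitochondria
VDAC1	mitochondria
CILSYN129	mitochondria
CILSYN130	mitochondria
CILSYN131	mitochondria
CILSYN132	mitochondria
MAPRE1	centrosome
PCNT	centrosome
CEP63	centrosome
CEP72	centrosome
CETN2	centrosome
CETN3	centrosome
CEP41	centrosome
CEP97	centrosome
CCP110	centrosome
CEP76	centrosome
CEP135	centrosome
CEP250	centrosome
NEK2	centrosome
PLK1	centrosome
CILSYN133	centrosome
CILSYN134	centrosome
CILSYN135	centrosome
CILSYN136	centrosome
CILSYN137	centrosome
CILSYN138	centrosome
CILSYN139	centrosome
CILSYN140	centrosome
CILSYN141	centrosome
CILSYN142	centrosome
CILSYN143	centrosome
CILSYN144	centrosome
CILSYN145	centrosome
CILSYN146	centrosome
CILSYN147	centrosome
CILSYN148	centrosome
CILSYN149	centrosome
CILSYN150	centrosome
CILSYN151	centrosome
CILSYN152	centrosome
CILSYN153	centrosome
CILSYN154	centrosome
CILSYN155	centrosome
CILSYN156	centrosome
CILSYN157	centrosome
CILSYN158	centrosome
MYO15A	other
TRANK1	other
TULP2	other
FBLN2	other
CILSYN159	other
CILSYN160	other
CILSYN161	other
CILSYN162	other
CILSYN163	other
CILSYN164	other
CILSYN165	other
CILSYN166	other
CILSYN167	other
CILSYN168	other
CILSYN169	other
CILSYN170	other
CILSYN171	other
CILSYN172	other
CILSYN173	other
CILSYN174	other
CILSYN175	other
CILSYN176	other
CILSYN177	other
CILSYN178	other
CILSYN179	other
CILSYN180	other
CILSYN181	other
CILSYN182	other
CILSYN183	other
CILSYN184	other
CILSYN185	other
CILSYN186	other
CILSYN187	other
CILSYN188	other
CILSYN189	other
CILSYN190	other
CILSYN191	other
CILSYN192	other
CILSYN193	other
CILSYN194	other
CILSYN195	other
CILSYN196	other
CILSYN197	other
CILSYN198	other
CILSYN199	other
CILSYN200	other
CILSYN201	other
CILSYN202	other
CILSYN203	other
CILSYN204	other
CILSYN205	other
CILSYN206	other
CILSYN207	other
CILSYN208	other
CILSYN209	other
CILSYN210	other
CILSYN211	other
CILSYN212	other
CILSYN213	other
CILSYN214	other
CILSYN215	other
CILSYN216	other
CILSYN217	other
CILSYN218	other
CILSYN219	other
CILSYN220	other
CILSYN221	other
CILSYN222	other
CILSYN223	other
CILSYN224	other
CILSYN225	other
CILSYN226	other
CILSYN227	other
CILSYN228	other
CILSYN229	other
CILSYN230	other
CILSYN231	other
CILSYN232	other
CILSYN233	other
CILSYN234	other
CILSYN235	other
CILSYN236	other
CILSYN237	other
CILSYN238	other
CILSYN239	other
CILSYN240	other
CILSYN241	other
CILSYN242	other
CILSYN243	other
CILSYN244	other
CILSYN245	other
CILSYN246	other
CILSYN247	other
CILSYN248	other
CILSYN249	other
CILSYN250	other
CILSYN251	other
CILSYN252	other
CILSYN253	other
CILSYN254	other
CILSYN255	other
CILSYN256	other
CILSYN257	other
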