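# Synthetic reconstruction of the histone-PTM reaction sets added to the
# genome-scale yeast model: 6 acetylation reactions (ATP-citrate-lyase route
# with nuclear diffusion of acetyl-CoA/CoA and an acetylated-histone demand),
# 10 methylation reactions (methionine cycle with exchanges for its
# metabolites and a methylated-histone demand), and the lumped glycogen
# consumption reaction. Stoichiometries are a plausible reconstruction, not a
# measured inventory; bounds in mmol gDW-1 h-1.
id	name	equation	lower_bound	upper_bound	subsystem	gpr	tag
ACL	ATP citrate lyase	cit_c + atp_c + coa_c --> accoa_c + oaa_c + adp_c + pi_c	0	1000	Citrate metabolism	ACL1	acetylation
ACCOAtn	acetyl-CoA nuclear diffusion	accoa_c <=> accoa_n	-1000	1000	Nuclear transport		acetylation
COAtn	coenzyme A nuclear diffusion	coa_n <=> coa_c	-1000	1000	Nuclear transport		acetylation
HISTAT	histone acetyltransferase	accoa_n --> coa_n + histac_n	0	1000	Histone acetylation	HAT1	acetylation
DM_histac	acetylated-histone demand	histac_n -->	0	1000	Histone acetylation		acetylation
DM_oaa	oxaloacetate demand	oaa_c -->	0	1000	Citrate metabolism		acetylation
METAT	methionine adenosyltransferase	met_L_c + atp_c + h2o_c --> amet_c + pi_c + ppi_c	0	1000	Methionine cycle	SAM1	methylation
AMETtn	S-adenosylmethionine nuclear diffusion	amet_c <=> amet_n	-1000	1000	Nuclear transport		methylation
HISTMT	histone methyltransferase	amet_n --> ahcys_n + histme_n	0	1000	Histone methylation	SET1	methylation
DM_histme	methylated-histone demand	histme_n -->	0	1000	Histone methylation		methylation
AHCYStn	S-adenosylhomocysteine nuclear diffusion	ahcys_n <=> ahcys_c	-1000	1000	Nuclear transport		methylation
AHCYSHYD	adenosylhomocysteinase	ahcys_c + h2o_c --> hcys_L_c + adn_c	0	1000	Methionine cycle	SAH1	methylation
METSYN	methionine synthase	hcys_L_c + 5mthf_c --> met_L_c + thf_c	0	1000	Methionine cycle	MET6	methylation
MTHFR_lump	methyl-THF regeneration (lumped)	thf_c --> 5mthf_c	0	1000	Methionine cycle	MET13	methylation
EX_met_L	L-methionine exchange	met_L_c <=>	-10	0	Exchange		methylation
EX_adn	adenosine exchange	adn_c <=>	0	1000	Exchange		methylation
GLYCDEG	glycogen consumption (lumped phosphorolysis)	glycogen_c --> glc_D_c	0	1000	Storage carbohydrate	GPH1	storage
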