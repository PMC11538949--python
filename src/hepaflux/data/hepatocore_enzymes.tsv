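reaction_id	protein_id
glucose_transport	Slc2a2
glucokinase	Gck
g6pase	G6pc1
glycolysis_upper	Gpi
glycolysis_upper	Pfkl
glycolysis_upper	Aldob
glycolysis_lower	Gapdh
glycolysis_lower	Pgk1
glycolysis_lower	Eno1
glycolysis_lower	Pklr
pyruvate_carboxylase	Pc
pepck	Pck1
pepck	Fbp1
glycogen_synthase	Gys2
glycogen_phosphorylase	Pygl
fructose_uptake	Khk
fructose_uptake	Aldob
galactose_uptake	Galk1
galactose_uptake	Galt
galactose_uptake	Gale
glycerol_uptake	Aqp9
glycerol_uptake	Gk
g3p_shuttle	Gpd1
lactate_exchange	Slc16a1
lactate_exchange	Ldha
pdh	Pdha1
pdh	Pdhb
pdh	Dlat
fatty_acid_uptake	Cd36
fatty_acid_uptake	Slc27a2
fatty_acid_uptake	Slc27a5
acc	Acaca
fatty_acid_synthesis	Fasn
beta_oxidation	Cpt1a
beta_oxidation	Cpt2
beta_oxidation	Acads
beta_oxidation	Acadl
beta_oxidation	Acadm
beta_oxidation	Hadha
ketogenesis	Hmgcs2
ketogenesis	Hmgcl
ketogenesis	Bdh1
tag_synthesis	Gpam
tag_synthesis	Agpat2
tag_synthesis	Dgat1
tag_synthesis	Dgat2
lipolysis	Pnpla2
lipolysis	Lipe
lipolysis	Abhd5
lipolysis	Plin3
vldl_export	Mttp
vldl_export	Apob
tca_oxphos	Cs
tca_oxphos	Idh3a
tca_oxphos	Sdha
tca_oxphos	Mdh2
ammonia_transport	Rhbg
urea_cycle	Cps1
urea_cycle	Otc
urea_cycle	Slc25a15
urea_cycle	Ass1
urea_cycle	Asl
urea_cycle	Arg1
urea_cycle	Nags
glutaminase	Gls2
glutamate_transport	Slc1a2
gdh	Glud1
ethanol_uptake	Adh1
aldh	Aldh2
aldh	Acss2
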