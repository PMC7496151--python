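compound,abbrev,kind,lb,ub
"1,3-Butadiene",but,bmd,30.3,56
Acrylonitrile,can,rpf,5.76,192
Allyl glycidyl ether,age,rpf,0.089,2.69
Acetaldehyde,ald,rpf,0.469,0.931
Alpha-methyl styrene,ams,rpf,0.583,5.39
Benzo[a]pyrene,bap,rpf,29.3,187
"1,2-Dibromo-3-chloropropane",dbcp,rpf,8.95,26.6
"1,2-Dibromoethane",dbe,rpf,0.575,1.67
Decalin,dcn,rpf,0.0175,0.11
Ethylene oxide,eox,rpf,21.7,71.5
Formaldehyde,fal,rpf,68.2,129
Hydrazine,hyr,rpf,5.65,560
Isobutyl nitrite,isn,rpf,0.176,3.7
Naphthalene,nap,rpf,0.339,0.726
Nitrobenzene,nbz,rpf,0.115,11.3
Propylene glycol mono-t-butyl ether,pge,rpf,0.61,5.9
Propylene oxide,prp,rpf,1.85,22.8
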