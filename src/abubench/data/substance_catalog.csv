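substance_code,ab_class,is_critical,carryover_days
amoxicillin,penicillin,false,0
ampicillin,penicillin,false,0
benzylpenicillin,penicillin,false,0
clavulanic_acid,beta_lactamase_inhibitor,false,0
cefalexin,cephalosporin_1g,false,0
cefazolin,cephalosporin_1g,false,0
cefovecin,cephalosporin_3g,true,13
ceftiofur,cephalosporin_3g,true,7
cefquinome,cephalosporin_4g,true,1
enrofloxacin,fluoroquinolone,true,0
marbofloxacin,fluoroquinolone,true,0
pradofloxacin,fluoroquinolone,true,0
azithromycin,macrolide,true,3
erythromycin,macrolide,true,0
tylosin,macrolide,true,0
doxycycline,tetracycline,false,0
oxytetracycline,tetracycline,false,2
metronidazole,nitroimidazole,false,0
clindamycin,lincosamide,false,0
gentamicin,aminoglycoside,false,0
trimethoprim,diaminopyrimidine,false,0
sulfadiazine,sulfonamide,false,0
sulfamethoxazole,sulfonamide,false,0
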