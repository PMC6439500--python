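source,destination,year,propagule_size,notes
Argentina,USA: Florida,1971,10,surviving adults from Campana Lagoon shipment; a 1975 mixed shipment of 219 is excluded (release unconfirmed)
Argentina,USA: Florida,1971,156,surviving adults from Santa Fe shipment
USA: Florida,Louisiana,1975,500,size undocumented; nominal
USA: Florida,Australia,1975,500,size undocumented; nominal
Louisiana,USA: Texas,1981,500,documented import released at Wallisville
USA: Texas,USA: California,1982,7500,size documented; year approximate
USA: Florida,SA: Wolseley,1985,500,size undocumented; nominal
USA: Florida,SA: Kubusi River,1985,500,size undocumented; nominal
Australia,SA: George,1990,500,size undocumented; nominal
Australia,Uganda,1995,500,Lake Victoria releases; size undocumented; nominal
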