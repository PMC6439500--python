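source,destination,year,propagule_size,notes
Argentina,USA: Florida,1974,156,surviving adults from Campana Lagoon shipment
Argentina,USA: Florida,1974,1050,surviving adults from Dique Lujan shipment
USA: Florida,USA: Texas,1980,50,documented release at Wallisville Reservoir
USA: Florida,Australia,1980,500,size undocumented; nominal
USA: Texas,USA: California,1982,2823,size documented; year approximate
Australia,SA: Wolseley,1989,500,size undocumented; nominal
Australia,SA: Enseleni,1990,500,size undocumented; nominal; genetic evidence suggests an additional untested source
SA: Wolseley,Uganda,1995,500,Lake Victoria releases; size undocumented; nominal
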