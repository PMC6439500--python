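location,site_id,n_bruchi,n_eichhorniae
Australia,AU,21,20
China,CH,,23
Singapore,SI,,33
SA: George,SAG,,22
SA: Wolseley,SAW,6,23
SA: Enseleni,SAE,18,
SA: Kubusi River,SAK,,22
Uganda,UG,26,26
Uruguay,UR,29,31
USA: California,CA,25,24
USA: Florida,FL,21,21
USA: Texas,TX,25,22
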