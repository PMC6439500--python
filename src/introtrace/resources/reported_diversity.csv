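species,population,A_R,A_p,H_E,H_O,F_IS,P_HWE,g2,P_g2
bruchi,Australia,2.43,0,0.39,0.35,0.10,0.16,0.06,0.19
bruchi,SA: Wolseley,2.88,0,0.50,0.52,-0.04,0.38,0.01,0.47
bruchi,SA: Enseleni,3.13,3,0.54,0.42,0.21,0.01,0.02,0.35
bruchi,Uganda,2.53,1,0.42,0.40,0.05,0.05,0.01,0.48
bruchi,Uruguay,3.11,8,0.42,0.33,0.22,0.00,-0.05,0.83
bruchi,USA: California,2.76,1,0.45,0.38,0.15,0.09,0.11,0.04
bruchi,USA: Florida,2.63,0,0.42,0.36,0.14,0.49,0.10,0.10
bruchi,USA: Texas,2.56,0,0.42,0.39,0.07,0.02,-0.01,0.60
eichhorniae,Australia,3.42,0,0.48,0.42,0.12,0.05,-0.03,0.78
eichhorniae,China,2.74,0,0.45,0.46,-0.02,0.47,0.02,0.29
eichhorniae,Singapore,3.47,1,0.49,0.43,0.11,0.00,0.01,0.44
eichhorniae,SA: George,2.49,1,0.34,0.32,0.07,0.86,0.11,0.05
eichhorniae,SA: Wolseley,4.17,0,0.56,0.44,0.22,0.00,0.10,0.02
eichhorniae,SA: Kubusi River,4.02,0,0.55,0.50,0.08,0.08,-0.02,0.84
eichhorniae,Uganda,3.93,1,0.53,0.50,0.07,0.05,0.01,0.34
eichhorniae,Uruguay,5.16,10,0.56,0.50,0.10,0.00,0.04,0.09
eichhorniae,USA: California,4.00,4,0.53,0.54,-0.02,0.13,0.11,0.05
eichhorniae,USA: Florida,4.43,2,0.57,0.48,0.15,0.00,0.00,0.48
eichhorniae,USA: Texas,4.26,0,0.56,0.49,0.13,0.84,-0.01,0.67
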