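statistic,pop_a,pop_b,value
FST,USA: California,Australia,0.03
FST,USA: Florida,Australia,0.02
FST,USA: Florida,USA: California,0.04
FST,SA: Wolseley,Australia,0.04
FST,SA: Wolseley,USA: California,0.04
FST,SA: Wolseley,USA: Florida,0.04
FST,SA: Enseleni,Australia,0.07
FST,SA: Enseleni,USA: California,0.05
FST,SA: Enseleni,USA: Florida,0.08
FST,SA: Enseleni,SA: Wolseley,0.04
FST,USA: Texas,Australia,0.10
FST,USA: Texas,USA: California,0.05
FST,USA: Texas,USA: Florida,0.09
FST,USA: Texas,SA: Wolseley,0.10
FST,USA: Texas,SA: Enseleni,0.08
FST,Uganda,Australia,0.01
FST,Uganda,USA: California,0.03
FST,Uganda,USA: Florida,0.03
FST,Uganda,SA: Wolseley,0.04
FST,Uganda,SA: Enseleni,0.07
FST,Uganda,USA: Texas,0.09
FST,Uruguay,Australia,0.06
FST,Uruguay,USA: California,0.04
FST,Uruguay,USA: Florida,0.08
FST,Uruguay,SA: Wolseley,0.05
FST,Uruguay,SA: Enseleni,0.09
FST,Uruguay,USA: Texas,0.07
FST,Uruguay,Uganda,0.06
JostD,USA: California,Australia,0.03
JostD,USA: Florida,Australia,0.02
JostD,USA: Florida,USA: California,0.04
JostD,SA: Wolseley,Australia,0.05
JostD,SA: Wolseley,USA: California,0.07
JostD,SA: Wolseley,USA: Florida,0.06
JostD,SA: Enseleni,Australia,0.11
JostD,SA: Enseleni,USA: California,0.08
JostD,SA: Enseleni,USA: Florida,0.13
JostD,SA: Enseleni,SA: Wolseley,0.08
JostD,USA: Texas,Australia,0.14
JostD,USA: Texas,USA: California,0.07
JostD,USA: Texas,USA: Florida,0.12
JostD,USA: Texas,SA: Wolseley,0.24
JostD,USA: Texas,SA: Enseleni,0.15
JostD,Uganda,Australia,0.00
JostD,Uganda,USA: California,0.04
JostD,Uganda,USA: Florida,0.02
JostD,Uganda,SA: Wolseley,0.06
JostD,Uganda,SA: Enseleni,0.12
JostD,Uganda,USA: Texas,0.13
JostD,Uruguay,Australia,0.08
JostD,Uruguay,USA: California,0.05
JostD,Uruguay,USA: Florida,0.11
JostD,Uruguay,SA: Wolseley,0.12
JostD,Uruguay,SA: Enseleni,0.16
JostD,Uruguay,USA: Texas,0.10
JostD,Uruguay,Uganda,0.08
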