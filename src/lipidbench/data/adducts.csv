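# Ionizing adducts: delta_formula is the atom gain/loss relative to the
# neutral molecule ("-" prefix denotes loss); charge sign fixes polarity.
name,delta_formula,charge
[M+H]1+,H,1
[M+2H]2+,H2,2
[M+NH4]1+,NH4,1
[M+Na]1+,Na,1
[M-H]1-,-H,-1
[M-2H]2-,-H2,-2
[M+HCOO]1-,CHO2,-1
[M+CH3COO]1-,C2H3O2,-1
[M-CH3]1-,-CH3,-1
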