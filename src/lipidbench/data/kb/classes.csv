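# Lipid class definitions (precursor level).
# scaffold_formula: neutral species = scaffold + sum of chain residues, where an
#   esterified/amidated acyl C:db;OH contributes C(c)H(2c-2db-1)O(1+OH), an
#   O-alkyl (plasmanyl) chain C(c)H(2c+1-2db)O(OH), a P-alkenyl (plasmenyl)
#   chain C(c)H(2c-1-2db)O(OH), and a long-chain base C(c)H(2c+3-2db)NO(OH).
#   Ester/amide water loss is accounted in the scaffold, not per chain.
# head_group_formula: the free (neutral) head group used by the HG rule token.
# Ranges are inclusive "lo-hi"; lists are ";"-separated.
category,class_name,n_acyl_slots,has_lcb,scaffold_formula,head_group_formula,adducts_pos,adducts_neg,fa_carbons,fa_double_bonds,fa_hydroxyls,fa_bond_types,lcb_carbons,lcb_double_bonds,lcb_hydroxyls,provenance
PL,PC,2,0,C8H18NO6P,C5H14NO4P,[M+H]1+;[M+Na]1+,[M+HCOO]1-;[M+CH3COO]1-;[M-CH3]1-,2-26,0-6,0-1,acyl;ether;vinyl,,,,Bruegger et al. 1997 PNAS 94:2339
PL,LPC,1,0,C8H19NO6P,C5H14NO4P,[M+H]1+;[M+Na]1+,[M+HCOO]1-;[M-CH3]1-,2-26,0-6,0-1,acyl;ether,,,,Bruegger et al. 1997 PNAS 94:2339
PL,PE,2,0,C5H12NO6P,C2H8NO4P,[M+H]1+,[M-H]1-,2-26,0-6,0-1,acyl;ether;vinyl,,,,Hsu & Turk 2009 J Chromatogr B 877:2673
PL,LPE,1,0,C5H13NO6P,C2H8NO4P,[M+H]1+,[M-H]1-,2-26,0-6,0-1,acyl;ether,,,,Hsu & Turk 2009 J Chromatogr B 877:2673
PL,PA,2,0,C3H7O6P,H3O4P,[M+H]1+;[M+NH4]1+,[M-H]1-,2-26,0-6,0-1,acyl,,,,Hsu & Turk 2009 J Chromatogr B 877:2673
PL,LPA,1,0,C3H8O6P,H3O4P,[M+H]1+,[M-H]1-,2-26,0-6,0-1,acyl,,,,Hsu & Turk 2009 J Chromatogr B 877:2673
PL,PG,2,0,C6H13O8P,C3H9O6P,[M+H]1+;[M+NH4]1+,[M-H]1-,2-26,0-6,0-1,acyl,,,,Hsu & Turk 2009 J Chromatogr B 877:2673
PL,LPG,1,0,C6H14O8P,C3H9O6P,[M+NH4]1+,[M-H]1-,2-26,0-6,0-1,acyl,,,,Hsu & Turk 2009 J Chromatogr B 877:2673
PL,PI,2,0,C9H17O11P,C6H13O9P,[M+NH4]1+,[M-H]1-,2-26,0-6,0-1,acyl,,,,Hsu & Turk 2000 JASMS 11:986
PL,LPI,1,0,C9H18O11P,C6H13O9P,[M+NH4]1+,[M-H]1-,2-26,0-6,0-1,acyl,,,,Hsu & Turk 2000 JASMS 11:986
PL,PS,2,0,C6H12NO8P,C3H8NO6P,[M+H]1+,[M-H]1-,2-26,0-6,0-1,acyl,,,,Hsu & Turk 2005 JASMS 16:1510
PL,LPS,1,0,C6H13NO8P,C3H8NO6P,[M+H]1+,[M-H]1-,2-26,0-6,0-1,acyl,,,,Hsu & Turk 2005 JASMS 16:1510
PL,CL,4,0,C9H18O13P2,C3H9O6P,[M+NH4]1+,[M-H]1-;[M-2H]2-,2-26,0-6,0-1,acyl,,,,Hsu et al. 2005 JASMS 16:491
GL,TG,3,0,C3H5O3,C3H8O3,[M+NH4]1+;[M+Na]1+,,2-26,0-6,0-1,acyl,,,,Murphy 2015 Tandem MS of Lipids ch.5
GL,DG,2,0,C3H6O3,C3H8O3,[M+NH4]1+;[M+Na]1+,,2-26,0-6,0-1,acyl,,,,Murphy 2015 Tandem MS of Lipids ch.5
GL,MG,1,0,C3H7O3,C3H8O3,[M+NH4]1+,,2-26,0-6,0-1,acyl,,,,Murphy 2015 Tandem MS of Lipids ch.5
SP,Cer,1,1,-H,,[M+H]1+,[M-H]1-;[M+HCOO]1-,2-26,0-6,0-2,acyl,14-22,0-2,1-3,Hsu & Turk 2002 JASMS 13:558
SP,SM,1,1,C5H11NO3P,C5H14NO4P,[M+H]1+,[M+HCOO]1-;[M-CH3]1-,2-26,0-6,0-1,acyl,14-22,0-2,1-3,Hsu & Turk 2000 JASMS 11:437
SP,HexCer,1,1,C6H9O5,C6H12O6,[M+H]1+,[M-H]1-;[M+HCOO]1-,2-26,0-6,0-2,acyl,14-22,0-2,1-3,Hsu & Turk 2002 JASMS 13:558
ST,ChE,1,0,C27H45O,C27H46O,[M+NH4]1+;[M+Na]1+,,2-26,0-6,0-1,acyl,,,,Murphy 2015 Tandem MS of Lipids ch.10
LM,FA,1,0,HO,,,[M-H]1-,2-26,0-6,0-3,acyl,,,,Murphy 2015 Tandem MS of Lipids ch.2
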