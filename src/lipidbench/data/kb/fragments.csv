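# Fragment calculation rules (fragment level).
# expression: comma-separated signed terms over the tokens PRECURSOR, HG,
#   FA1..FA4, LCB (free building-block formulas) and literal formulas, e.g.
#   "PRECURSOR +1, H +1, FA1 -1" = protonated precursor minus the free fatty
#   acid.  The resolved formula is the atom composition of the charged
#   fragment; m/z = (mass - charge*m_e)/|charge|.
# Users extend assays by appending rows here (or to a sibling user CSV).
class_name,fragment_name,polarity,charge,expression,provenance
PC,HG 184 (phosphocholine),+,1,C5H15NO4P +1,Bruegger et al. 1997 PNAS 94:2339
PC,NL183 [M+H-HG],+,1,"PRECURSOR +1, H +1, C5H14NO4P -1",Murphy 2015 Tandem MS of Lipids ch.6
PC,FA1 carboxylate,-,-1,"FA1 +1, H -1",Hsu & Turk 2009 J Chromatogr B 877:2673
PC,FA2 carboxylate,-,-1,"FA2 +1, H -1",Hsu & Turk 2009 J Chromatogr B 877:2673
PC,[M-CH3] demethyl,-,-1,"PRECURSOR +1, CH3 -1",Hsu & Turk 2009 J Chromatogr B 877:2673
LPC,HG 184 (phosphocholine),+,1,C5H15NO4P +1,Bruegger et al. 1997 PNAS 94:2339
LPC,FA1 carboxylate,-,-1,"FA1 +1, H -1",Hsu & Turk 2009 J Chromatogr B 877:2673
PE,NL141 [M+H-HG],+,1,"PRECURSOR +1, H +1, C2H8NO4P -1",Hsu & Turk 2009 J Chromatogr B 877:2673
PE,FA1 carboxylate,-,-1,"FA1 +1, H -1",Hsu & Turk 2009 J Chromatogr B 877:2673
PE,FA2 carboxylate,-,-1,"FA2 +1, H -1",Hsu & Turk 2009 J Chromatogr B 877:2673
PE,HG 140 (phosphoethanolamine),-,-1,C2H7NO4P +1,Hsu & Turk 2009 J Chromatogr B 877:2673
LPE,NL141 [M+H-HG],+,1,"PRECURSOR +1, H +1, C2H8NO4P -1",Hsu & Turk 2009 J Chromatogr B 877:2673
LPE,FA1 carboxylate,-,-1,"FA1 +1, H -1",Hsu & Turk 2009 J Chromatogr B 877:2673
PA,FA1 carboxylate,-,-1,"FA1 +1, H -1",Hsu & Turk 2009 J Chromatogr B 877:2673
PA,FA2 carboxylate,-,-1,"FA2 +1, H -1",Hsu & Turk 2009 J Chromatogr B 877:2673
PA,GP 153 (glycerophosphate-H2O),-,-1,C3H6O5P +1,Hsu & Turk 2009 J Chromatogr B 877:2673
LPA,FA1 carboxylate,-,-1,"FA1 +1, H -1",Hsu & Turk 2009 J Chromatogr B 877:2673
LPA,GP 153 (glycerophosphate-H2O),-,-1,C3H6O5P +1,Hsu & Turk 2009 J Chromatogr B 877:2673
PG,FA1 carboxylate,-,-1,"FA1 +1, H -1",Hsu & Turk 2009 J Chromatogr B 877:2673
PG,FA2 carboxylate,-,-1,"FA2 +1, H -1",Hsu & Turk 2009 J Chromatogr B 877:2673
PG,GP 153 (glycerophosphate-H2O),-,-1,C3H6O5P +1,Hsu & Turk 2009 J Chromatogr B 877:2673
PG,NL172 [M+H-HG],+,1,"PRECURSOR +1, H +1, C3H9O6P -1",Murphy 2015 Tandem MS of Lipids ch.6
LPG,FA1 carboxylate,-,-1,"FA1 +1, H -1",Hsu & Turk 2009 J Chromatogr B 877:2673
PI,FA1 carboxylate,-,-1,"FA1 +1, H -1",Hsu & Turk 2000 JASMS 11:986
PI,FA2 carboxylate,-,-1,"FA2 +1, H -1",Hsu & Turk 2000 JASMS 11:986
PI,IP 241 (inositolphosphate-H2O),-,-1,C6H10O8P +1,Hsu & Turk 2000 JASMS 11:986
PI,NL277 [M+NH4-HG-NH3],+,1,"PRECURSOR +1, H +1, C6H13O9P -1",Hsu & Turk 2000 JASMS 11:986
LPI,FA1 carboxylate,-,-1,"FA1 +1, H -1",Hsu & Turk 2000 JASMS 11:986
LPI,IP 241 (inositolphosphate-H2O),-,-1,C6H10O8P +1,Hsu & Turk 2000 JASMS 11:986
PS,NL87 [M-H-serine],-,-1,"PRECURSOR +1, H -1, C3H5NO2 -1",Hsu & Turk 2005 JASMS 16:1510
PS,FA1 carboxylate,-,-1,"FA1 +1, H -1",Hsu & Turk 2005 JASMS 16:1510
PS,FA2 carboxylate,-,-1,"FA2 +1, H -1",Hsu & Turk 2005 JASMS 16:1510
PS,NL185 [M+H-HG],+,1,"PRECURSOR +1, H +1, C3H8NO6P -1",Hsu & Turk 2005 JASMS 16:1510
LPS,NL87 [M-H-serine],-,-1,"PRECURSOR +1, H -1, C3H5NO2 -1",Hsu & Turk 2005 JASMS 16:1510
LPS,FA1 carboxylate,-,-1,"FA1 +1, H -1",Hsu & Turk 2005 JASMS 16:1510
CL,FA1 carboxylate,-,-1,"FA1 +1, H -1",Hsu et al. 2005 JASMS 16:491
CL,FA2 carboxylate,-,-1,"FA2 +1, H -1",Hsu et al. 2005 JASMS 16:491
CL,FA3 carboxylate,-,-1,"FA3 +1, H -1",Hsu et al. 2005 JASMS 16:491
CL,FA4 carboxylate,-,-1,"FA4 +1, H -1",Hsu et al. 2005 JASMS 16:491
TG,NL FA1 [M+H-FA1],+,1,"PRECURSOR +1, H +1, FA1 -1",Murphy 2015 Tandem MS of Lipids ch.5
TG,NL FA2 [M+H-FA2],+,1,"PRECURSOR +1, H +1, FA2 -1",Murphy 2015 Tandem MS of Lipids ch.5
TG,NL FA3 [M+H-FA3],+,1,"PRECURSOR +1, H +1, FA3 -1",Murphy 2015 Tandem MS of Lipids ch.5
DG,[M+H-H2O],+,1,"PRECURSOR +1, H +1, H2O -1",Murphy 2015 Tandem MS of Lipids ch.5
DG,NL FA1 [M+H-FA1],+,1,"PRECURSOR +1, H +1, FA1 -1",Murphy 2015 Tandem MS of Lipids ch.5
DG,NL FA2 [M+H-FA2],+,1,"PRECURSOR +1, H +1, FA2 -1",Murphy 2015 Tandem MS of Lipids ch.5
MG,[M+H-H2O],+,1,"PRECURSOR +1, H +1, H2O -1",Murphy 2015 Tandem MS of Lipids ch.5
Cer,LCB W' [LCB+H-2H2O],+,1,"LCB +1, H +1, H2O -2",Hsu & Turk 2002 JASMS 13:558
Cer,[M+H-H2O],+,1,"PRECURSOR +1, H +1, H2O -1",Hsu & Turk 2002 JASMS 13:558
Cer,NL FA ketene [M-H-FA+H2O],-,-1,"PRECURSOR +1, H -1, FA1 -1, H2O +1",Hsu & Turk 2002 JASMS 13:558
SM,HG 184 (phosphocholine),+,1,C5H15NO4P +1,Hsu & Turk 2000 JASMS 11:437
SM,[M+H-H2O],+,1,"PRECURSOR +1, H +1, H2O -1",Hsu & Turk 2000 JASMS 11:437
SM,[M-CH3] demethyl,-,-1,"PRECURSOR +1, CH3 -1",Hsu & Turk 2000 JASMS 11:437
HexCer,NL Hex [M+H-162],+,1,"PRECURSOR +1, H +1, C6H10O5 -1",Hsu & Turk 2002 JASMS 13:558
HexCer,LCB W' [LCB+H-2H2O],+,1,"LCB +1, H +1, H2O -2",Hsu & Turk 2002 JASMS 13:558
HexCer,NL FA ketene [M-H-FA+H2O],-,-1,"PRECURSOR +1, H -1, FA1 -1, H2O +1",Hsu & Turk 2002 JASMS 13:558
ChE,cholestadienyl 369,+,1,C27H45 +1,Murphy 2015 Tandem MS of Lipids ch.10
FA,[M-H-H2O],-,-1,"PRECURSOR +1, H -1, H2O -1",Murphy 2015 Tandem MS of Lipids ch.2
FA,[M-H-CO2],-,-1,"PRECURSOR +1, H -1, CO2 -1",Murphy 2015 Tandem MS of Lipids ch.2
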