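# Monoisotopic masses, IUPAC 2021 atomic mass evaluation (Da).
# Heavy isotopes are distinct pseudo-elements so labeled formulas reuse
# ordinary integer-count arithmetic.
symbol,mass
H,1.00782503207
[2H],2.01410177812
C,12.0
[13C],13.00335483521
N,14.00307400446
[15N],15.00010889894
O,15.99491461957
P,30.97376199768
S,31.97207117443
Na,22.98976928199
K,38.96370648643
Li,7.01600343666
Cl,34.96885268226
F,18.99840316207
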