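# MS instrument profiles for collision-energy modelling.
# min_reporting_ce: below this CE the dissociation profile is nearly flat on
# HCD Orbitrap-type instruments, so model-based predictions are not reported.
name,ce_unit,ce_min,ce_max,step,min_reporting_ce
hcd-orbitrap-nce,NCE,10,60,1,18
cid-qtof-volts,volts,10,100,1,10
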