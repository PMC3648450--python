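# w10s8: multiple spaced seed set designed by bond.seed_design
# design: weight=10 count=8 length_range=(13, 24) model=(N=50, p=0.85) random_seed=1 restarts=3
11**1*1***1****1**1**111
111***1***1**1***1*111
11*11***1*****1*1*111
1111*1****1*1**1*11
11*1**11*1****1111
111*1***11**1111
111*11*1**11*11
111*1*1111*11
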