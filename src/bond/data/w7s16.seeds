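# w7s16: multiple spaced seed set designed by bond.seed_design
# design: weight=7 count=16 length_range=(12, 19) model=(N=50, p=0.75) random_seed=0 restarts=3
11****1***1*****111
11**1****1*****1*11
11*1***1*****1**11
1*1**1******1*1*11
11*1*****1****111
11*1*1*****1***11
11**1***1***1*11
111****1***1*1*1
11**1*1****1*11
11***1*1**1**11
11*1****11**11
1*11***1**1*11
11*1**1*1**11
111**1**1*1*1
1*11**1**111
1*111***11*1
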