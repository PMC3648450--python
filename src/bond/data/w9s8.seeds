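# w9s8: multiple spaced seed set designed by bond.seed_design
# design: weight=9 count=8 length_range=(12, 22) model=(N=50, p=0.75) random_seed=3 restarts=3
11*1***1****1**1***111
111**1****1*****11*11
111**1***1**1**1*11
11*1**1***1*1*1*11
111***1*1**1*111
111*1*1**1**111
1111***11*111
11*111*1*111
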