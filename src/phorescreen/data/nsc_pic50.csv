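id,pic50
NSC35839,9.29
NSC80116,9.00
NSC143057,7.41
NSC164472,7.56
NSC281260,8.67
NSC636831,8.74
NSC659829,10.09
NSC702105,7.55
NSC711731,7.65
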