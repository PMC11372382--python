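# Synthetic template for a post-intervention rate-ratio schedule (NOT values from
# any published evaluation -- transcribe the literature estimates you intend to use).
# k = years since the intervention; rr_target applies to the restricted means,
# rr_other to all remaining means (substitution).
means,k,rr_target,rr_target_lo,rr_target_hi,rr_other,rr_other_lo,rr_other_hi
firearm,1,0.90,0.80,1.01,1.05,0.95,1.16
firearm,2,0.85,0.75,0.96,1.04,0.94,1.15
firearm,3,0.80,0.70,0.91,1.02,0.92,1.13
firearm,4,0.75,0.65,0.87,1.00,0.90,1.11
firearm,5,0.72,0.62,0.84,0.98,0.88,1.09
pesticide,1,0.70,0.58,0.85,1.08,0.96,1.22
pesticide,2,0.60,0.48,0.75,1.06,0.94,1.20
pesticide,3,0.52,0.40,0.68,1.03,0.91,1.17
pesticide,4,0.46,0.34,0.62,1.00,0.88,1.14
pesticide,5,0.42,0.30,0.59,0.97,0.85,1.11
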