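case,diagnosis,ta_ap,nft_pretangles,cb,threads
102,PSP,137,48,146,1
105,PSP,38,30,61,2
107,PSP,49,42,128,3
104,CBD,68,62,36,3
108,CBD,94,134,34,5
109,CBD,17,31,5,1
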