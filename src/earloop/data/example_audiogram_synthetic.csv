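frequency_hz,hl_db
125,15
250,15
500,20
750,25
1000,30
1500,40
2000,50
3000,60
4000,65
6000,70
8000,75
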