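plot,pct_beets_hit_close_to_potato
1,14
2,36
3,67
4,100
5,43
6,75
7,67
8,0
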