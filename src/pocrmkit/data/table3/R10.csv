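combination,prob
1.1.1,0.25
1.2.1,0.40
2.2.1,0.50
2.2.2,0.70
2.3.1,0.60
2.3.2,0.80
2.4.1,0.65
2.4.2,0.85
3.3.1,0.75
3.3.2,0.95
3.4.1,0.90
3.4.2,0.99
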