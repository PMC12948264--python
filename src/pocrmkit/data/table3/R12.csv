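combination,prob
1.1.1,0.01
1.2.1,0.10
2.2.1,0.25
2.2.2,0.40
2.3.1,0.50
2.3.2,0.65
2.4.1,0.60
2.4.2,0.70
3.3.1,0.75
3.3.2,0.80
3.4.1,0.85
3.4.2,0.90
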