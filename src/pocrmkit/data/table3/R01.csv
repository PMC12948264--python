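combination,prob
1.1.1,0.01
1.2.1,0.01
2.2.1,0.01
2.2.2,0.03
2.3.1,0.05
2.3.2,0.10
2.4.1,0.15
2.4.2,0.25
3.3.1,0.40
3.3.2,0.50
3.4.1,0.60
3.4.2,0.70
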