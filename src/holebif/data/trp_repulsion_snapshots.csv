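snapshot,e_interaction_eV
1 ps,1.6849
1000 ps,1.6939
2000 ps,1.7143
3000 ps,1.6074
4000 ps,1.6115
5000 ps,1.5676
6000 ps,1.5913
7000 ps,1.6618
8000 ps,1.6419
9000 ps,1.6403
10000 ps,1.5581
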