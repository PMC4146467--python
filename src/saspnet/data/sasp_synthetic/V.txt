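# synthetic reconstruction of the speract-activated signaling pathway network from the published wiring diagram and physiological balance rules (not a transcription of the original supplementary tables)
node: V
arity: 3
regulators: dNa dCa dK dCl V
0 0 0 0 0 1
0 0 0 0 1 1
0 0 0 0 2 1
0 0 0 1 0 0
0 0 0 1 1 0
0 0 0 1 2 1
0 0 1 0 0 0
0 0 1 0 1 0
0 0 1 0 2 1
0 0 1 1 0 0
0 0 1 1 1 0
0 0 1 1 2 1
0 1 0 0 0 1
0 1 0 0 1 2
0 1 0 0 2 2
0 1 0 1 0 1
0 1 0 1 1 1
0 1 0 1 2 1
0 1 1 0 0 1
0 1 1 0 1 1
0 1 1 0 2 1
0 1 1 1 0 0
0 1 1 1 1 0
0 1 1 1 2 1
1 0 0 0 0 1
1 0 0 0 1 2
1 0 0 0 2 2
1 0 0 1 0 1
1 0 0 1 1 1
1 0 0 1 2 1
1 0 1 0 0 1
1 0 1 0 1 1
1 0 1 0 2 1
1 0 1 1 0 0
1 0 1 1 1 0
1 0 1 1 2 1
1 1 0 0 0 1
1 1 0 0 1 2
1 1 0 0 2 2
1 1 0 1 0 1
1 1 0 1 1 2
1 1 0 1 2 2
1 1 1 0 0 1
1 1 1 0 1 2
1 1 1 0 2 2
1 1 1 1 0 1
1 1 1 1 1 1
1 1 1 1 2 1
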