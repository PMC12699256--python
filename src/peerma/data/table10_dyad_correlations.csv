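dyad_id,construct,rs,p
1,hope,0.96,<.001
1,sleep,0.97,<.001
1,fatigue,0.88,<.001
1,depression,0.78,.01
1,pain,0.90,<.001
2,hope,0.98,<.001
2,sleep,0.81,<.001
2,fatigue,1.00,<.001
2,depression,1.00,<.001
2,pain,0.96,<.001
3,hope,0.18,.40
3,sleep,0.29,.17
3,fatigue,0.80,<.001
3,depression,-0.13,.56
3,pain,0.48,.02
4,hope,0.11,.50
4,sleep,0.92,<.001
4,fatigue,0.71,<.001
4,depression,0.78,<.001
4,pain,-0.23,.16
5,hope,0.90,<.001
5,sleep,-0.71,<.001
5,fatigue,-1.00,<.001
5,depression,0.80,<.001
5,pain,-0.81,<.001
6,hope,0.62,<.001
6,sleep,0.15,.52
6,fatigue,-0.26,.22
6,depression,0.54,.01
6,pain,0.22,.36
7,hope,-0.50,.01
7,sleep,0.07,.72
7,fatigue,0.05,.79
7,depression,-0.23,.25
7,pain,0.52,.01
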