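dyad_id,construct,rs,p
1,hope,0.96,<.001
1,sleep,-0.49,<.001
1,fatigue,-0.61,<.001
1,depression,0.98,<.001
1,pain,-0.56,.04
2,hope,0.97,<.001
2,sleep,0.79,<.001
2,fatigue,-0.99,<.001
2,depression,-0.98,<.001
2,pain,-0.95,<.001
3,hope,0.18,.40
3,sleep,0.29,.17
3,fatigue,-0.80,<.001
3,depression,0.39,.06
3,pain,-0.48,.02
4,hope,0.01,.94
4,sleep,1.00,<.001
4,fatigue,-0.72,<.001
4,depression,-0.95,<.001
4,pain,-0.77,<.001
5,hope,0.91,<.001
5,sleep,0.76,<.001
5,fatigue,-0.85,<.001
5,depression,-0.83,<.001
5,pain,-0.88,<.001
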