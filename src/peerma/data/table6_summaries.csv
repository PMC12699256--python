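dyad_id,role,construct,median,mean,sd
1,patient,hope,0.69,0.64,0.30
1,patient,sleep,0.89,0.82,0.17
1,patient,fatigue,0.08,0.23,0.29
1,patient,depression,0.30,0.31,0.32
1,patient,pain,0.25,0.34,0.29
1,support_person,hope,0.81,0.71,0.29
1,support_person,sleep,0.75,0.72,0.14
1,support_person,fatigue,0.35,0.35,0.25
1,support_person,depression,0.14,0.31,0.38
1,support_person,pain,0.10,0.21,0.28
2,patient,hope,0.69,0.60,0.31
2,patient,sleep,0.85,0.72,0.28
2,patient,fatigue,0.35,0.43,0.35
2,patient,depression,0.34,0.40,0.30
2,patient,pain,0.27,0.38,0.34
2,support_person,hope,0.81,0.64,0.30
2,support_person,sleep,0.91,0.76,0.29
2,support_person,fatigue,0.12,0.27,0.26
2,support_person,depression,0.10,0.28,0.28
2,support_person,pain,0.21,0.32,0.27
3,patient,hope,0.69,0.64,0.32
3,patient,sleep,0.34,0.44,0.32
3,patient,fatigue,0.19,0.29,0.26
3,patient,depression,0.18,0.31,0.28
3,patient,pain,0.19,0.30,0.28
3,support_person,hope,0.69,0.64,0.32
3,support_person,sleep,0.46,0.50,0.37
3,support_person,fatigue,0.14,0.22,0.27
3,support_person,depression,0.21,0.29,0.30
3,support_person,pain,0.16,0.21,0.28
4,patient,hope,0.61,0.59,0.24
4,patient,sleep,0.76,0.69,0.29
4,patient,fatigue,0.16,0.35,0.36
4,patient,depression,0.12,0.19,0.21
4,patient,pain,0.19,0.31,0.32
4,support_person,hope,0.75,0.64,0.24
4,support_person,sleep,0.78,0.69,0.28
4,support_person,fatigue,0.52,0.55,0.21
4,support_person,depression,0.51,0.53,0.26
4,support_person,pain,0.61,0.59,0.23
5,patient,hope,0.50,0.50,0.50
5,patient,sleep,0.88,0.77,0.29
5,patient,fatigue,0.86,0.62,0.54
5,patient,depression,0.50,0.50,0.71
5,patient,pain,0.00,0.25,0.50
5,support_person,hope,0.69,0.66,0.14
5,support_person,sleep,0.77,0.75,0.15
5,support_person,fatigue,1.00,0.94,0.20
5,support_person,depression,1.00,0.87,0.27
5,support_person,pain,0.00,0.12,0.27
6,patient,hope,0.41,0.47,0.31
6,patient,sleep,0.66,0.60,0.26
6,patient,fatigue,0.75,0.60,0.29
6,patient,depression,0.44,0.36,0.24
6,patient,pain,0.36,0.39,0.30
6,support_person,hope,0.71,0.63,0.34
6,support_person,sleep,0.43,0.52,0.37
6,support_person,fatigue,0.73,0.61,0.40
6,support_person,depression,0.07,0.27,0.36
6,support_person,pain,0.74,0.57,0.41
7,patient,hope,0.81,0.77,0.24
7,patient,sleep,0.75,0.72,0.18
7,patient,fatigue,0.70,0.63,0.29
7,patient,depression,0.34,0.33,0.20
7,patient,pain,0.59,0.63,0.28
7,support_person,hope,0.29,0.39,0.49
7,support_person,sleep,0.86,0.68,0.46
7,support_person,fatigue,0.45,0.48,0.45
7,support_person,depression,0.36,0.43,0.49
7,support_person,pain,0.27,0.39,0.47
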