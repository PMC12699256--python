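participant_id,role,days,weeks,expected,answered_application,answered_self,response_rate,activity_days,sleep_days
1,patient,196,28.0,164,161,0,98,196,191
1,support_person,196,28.0,164,147,0,90,,
2,patient,169,24.1,140,0,69,49,127,95
2,support_person,169,24.1,140,0,91,65,,
3,patient,39,5.6,30,1,29,100,39,15
3,support_person,39,5.6,30,4,13,57,,
4,patient,76,10.9,59,2,26,47,11,4
4,support_person,76,10.9,59,9,61,119,,
5,patient,95,13.6,77,32,1,43,47,18
5,support_person,94,13.4,77,27,71,127,,
6,patient,174,24.9,140,17,25,30,0,0
6,support_person,162,23.1,135,14,7,16,,
7,patient,69,9.9,53,0,32,60,0,0
7,support_person,12,1.7,7,0,4,57,,
8,patient,195,27.9,158,117,2,75,2,2
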