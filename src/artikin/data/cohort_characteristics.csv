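subject,patient_sex,patient_age,disease_duration_y,dbs_months,control_sex,control_age
1,m,66,22,25,m,63
2,m,70,29,5,m,69
3,m,31,9,105,m,30
4,m,73,34,56,m,73
5,f,53,3,47,f,52
6,f,59,4,33,f,58
7,m,54,7,67,m,54
8,f,60,14,93,f,56
9,f,61,39,4,f,68
10,m,67,24,66,m,63
11,m,72,9,7,m,70
12,m,73,7,81,m,75
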