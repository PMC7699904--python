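# 30-patient case-study cohort: vitals as recorded plus the free-text
# history / other-factors notes shown to the expert team. Patient 16's
# SpO2 (65 %) lies below the modelled pulse-oximeter range and is flagged
# on load. Patients 25 and 26 have identical inputs as printed.
patient_id,spo2,heart_rate,temperature,history,other_factors
1,92,80,37,"55 y.o., sleep apnea and COPD","Mining job"
2,87,50,38.5,"60 y.o., smoker and sedentary",""
3,80,60,37.1,"47 y.o., lung cancer",""
4,93,140,38,"18 y.o., obesity and asthma",""
5,83,80,39,"78 y.o., ex-smoker",""
6,91,96,37.8,"24 y.o.",""
7,95,56,36.5,"15 y.o., asthma",""
8,90,72,36,"35 y.o., smoker","Stone work job"
9,89,55,35.9,"93 y.o., ex-smoker",""
10,75,50,38.5,"70 y.o., lung oedema",""
11,96,64,36.5,"25 y.o.",""
12,89,74,36.6,"26 y.o., smoker","Risky contacts"
13,92,56,37,"45 y.o., sporty",""
14,87,83,37.1,"44 y.o., post-surgery",""
15,80,63,35.8,"92 y.o.",""
16,65,50,35.8,"87 y.o., palliative care",""
17,86,92,37.2,"17 y.o., obesity",""
18,95,72,36.6,"49 y.o.",""
19,74,63,35.9,"50 y.o., alcoholic and smoker",""
20,93,89,37,"23 y.o.",""
21,89,66,36.7,"67 y.o., ex-smoker and sedentary",""
22,82,70,37.2,"52 y.o., post-surgery",""
23,92,68,36.3,"84 y.o., sporty",""
24,70,51,35.8,"77 y.o., lung cancer",""
25,89,66,36.3,"36 y.o., asthma",""
26,89,66,36.3,"36 y.o., asthma",""
27,87,94,37.2,"59 y.o., COPD",""
28,90,56,36.9,"43 y.o.",""
29,96,71,36.7,"38 y.o., smoker",""
30,82,84,36.4,"66 y.o., sleep apnea",""
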