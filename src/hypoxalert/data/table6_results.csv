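# Case-study simulation results: technical risk, expert risk and the
# (uncorrected) global risk as printed, with the recommended state at the
# 60-unit emergency limit and the patient's actual state. Recomputing RG
# from the printed (RT, RE) with the surface formulas reproduces the
# printed value within +-0.05 except for rows 11, 24 and 26 (print
# anomalies; see package documentation).
patient_id,technical_risk,expert_risk,global_risk,recommended_state,actual_state
1,43.33,90.00,72.45,Emergency,Non-emergency
2,80.00,74.40,94.00,Emergency,Emergency
3,90.00,90.00,97.92,Emergency,Emergency
4,61.84,53.62,87.01,Emergency,Non-emergency
5,81.47,90.00,98.01,Emergency,Emergency
6,45.11,10.00,45.25,Non-emergency,Emergency
7,38.59,10.00,38.67,Non-emergency,Non-emergency
8,57.21,40.16,80.84,Emergency,Emergency
9,55.93,69.08,92.28,Emergency,Emergency
10,90.00,90.00,97.92,Emergency,Emergency
11,34.10,34.13,34.13,Non-emergency,Non-emergency
12,56.67,90.00,97.85,Emergency,Emergency
13,43.72,40.46,44.59,Non-emergency,Non-emergency
14,56.67,90.00,97.85,Emergency,Emergency
15,90.00,90.00,97.90,Emergency,Emergency
16,90.00,90.00,97.90,Emergency,Emergency
17,57.62,40.00,80.76,Emergency,Non-emergency
18,40.68,10.00,40.75,Non-emergency,Non-emergency
19,90.00,90.00,97.90,Emergency,Emergency
20,43.33,10.00,43.43,Non-emergency,Non-emergency
21,56.67,31.33,75.59,Emergency,Non-emergency
22,65.67,56.06,87.98,Emergency,Emergency
23,43.33,29.66,43.72,Non-emergency,Non-emergency
24,90.00,90.00,97.70,Emergency,Emergency
25,56.67,22.51,68.61,Emergency,Emergency
26,56.59,40.00,87.74,Emergency,Emergency
27,55.92,16.33,61.82,Emergency,Non-emergency
28,33.47,20.00,33.54,Non-emergency,Non-emergency
29,64.63,56.78,88.24,Emergency,Emergency
30,52.83,35.94,78.41,Emergency,Non-emergency
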