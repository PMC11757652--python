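# Measurement campaign: exhaled Rn-219 after Ra-223 administration.
# One row per administration x time point; values are exhaled activity
# concentrations in kBq/l (decay-corrected, as tabulated), statuses are
# point / greater_than / less_than.  decay_factor is the tabulated in-tube
# decay correction; final_value/final_status are the tabulated combined
# results, kept for cross-checking the recombination rules.
# Administrations D1-D4 were recorded with the Alphaguard P30F, whose range
# limit (30 kBq/m^3) is far below exhaled Rn-219 levels; their readings were
# unusable and are not tabulated. These four rows are synthetic placeholders
# (no readings) standing in for the discarded datasets so that campaign
# filtering is exercised end to end.  Patient ids are arbitrary labels
# consistent with 21 administrations in 14 patients (at most two each).
admin_id,patient_id,activity_MBq,flow_l_min,instrument,decay_factor,timepoint,value_1,status_1,value_2,status_2,outlier_2,final_value,final_status
1,p01,4.37,4,PQ2000,1.054,early,4.61,greater_than,4.61,greater_than,False,4.61,greater_than
1,p01,4.37,4,PQ2000,1.054,late,4.82,greater_than,4.82,greater_than,False,4.82,greater_than
2,p02,4.36,4,PQ2000,1.054,early,4.61,point,4.61,point,False,4.61,point
2,p02,4.36,4,PQ2000,1.054,late,4.61,point,4.82,point,False,4.82,point
3,p03,4.87,4,PQ2000,1.054,early,4.82,point,4.82,point,False,4.82,point
3,p03,4.87,4,PQ2000,1.054,late,4.82,point,4.82,point,False,4.82,point
4,p04,3.10,4,PQ2000,1.054,early,4.85,greater_than,4.85,greater_than,False,4.85,greater_than
4,p04,3.10,4,PQ2000,1.054,late,3.87,point,1.45,less_than,True,3.87,point
5,p05,5.06,4,PQ2000,1.054,early,4.85,greater_than,4.85,greater_than,False,4.85,greater_than
5,p05,5.06,4,PQ2000,1.054,late,4.85,greater_than,4.29,point,False,4.29,greater_than
6,p06,3.33,1,PQ2000,1.234,early,5.37,point,5.37,point,False,5.37,point
6,p06,3.33,1,PQ2000,1.234,late,1.96,point,2.12,point,False,2.04,point
7,p07,3.99,1,PQ2000,1.234,early,5.68,greater_than,5.68,greater_than,False,5.68,greater_than
7,p07,3.99,1,PQ2000,1.234,late,4.63,point,4.43,point,False,4.53,point
8,p08,3.75,4,PQ2000,1.054,early,4.85,greater_than,4.85,greater_than,False,4.85,greater_than
8,p08,3.75,4,PQ2000,1.054,late,4.85,greater_than,4.85,greater_than,False,4.85,greater_than
9,p09,4.62,1,PQ2000,1.234,early,5.68,greater_than,5.68,greater_than,False,5.68,greater_than
9,p09,4.62,1,PQ2000,1.234,late,5.53,point,5.68,greater_than,False,5.53,greater_than
10,p10,4.43,1,PQ2000,1.234,early,5.68,greater_than,5.68,greater_than,False,5.68,greater_than
10,p10,4.43,1,PQ2000,1.234,late,5.68,greater_than,5.68,greater_than,False,5.68,greater_than
11,p11,5.49,1,PQ2000,1.234,early,5.68,greater_than,5.68,greater_than,False,5.68,greater_than
11,p11,5.49,1,PQ2000,1.234,late,4.42,point,3.66,point,False,4.04,point
12,p12,5.12,1,PQ2000,1.234,early,5.68,greater_than,5.68,greater_than,False,5.68,greater_than
12,p12,5.12,1,PQ2000,1.234,late,1.70,less_than,1.70,less_than,False,1.70,less_than
13,p13,4.89,1,PQ2000,1.234,early,5.68,greater_than,5.68,greater_than,False,5.68,greater_than
13,p13,4.89,1,PQ2000,1.234,late,3.28,point,3.04,point,False,3.16,point
14,p14,5.20,1,PQ2000,1.234,early,5.68,greater_than,5.68,greater_than,False,5.68,greater_than
14,p14,5.20,1,PQ2000,1.234,late,3.32,point,2.98,point,False,3.15,point
15,p01,3.77,4,PQ2000,1.054,early,4.85,point,4.18,point,False,4.51,point
15,p01,3.77,4,PQ2000,1.054,late,3.30,point,3.30,point,False,3.30,point
16,p02,3.74,4,PQ2000,1.054,early,4.85,greater_than,4.85,greater_than,False,4.85,greater_than
16,p02,3.74,4,PQ2000,1.054,late,4.85,greater_than,4.85,greater_than,False,4.85,greater_than
17,p03,4.33,4,PQ2000,1.054,late,2.58,point,2.39,point,False,2.48,point
D1,p04,,,P30F,,early,,,,,False,,
D2,p05,,,P30F,,early,,,,,False,,
D3,p06,,,P30F,,early,,,,,False,,
D4,p07,,,P30F,,early,,,,,False,,
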