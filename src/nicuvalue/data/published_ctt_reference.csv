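ctt_category,billing_group,priority_rank,cost_rank,variability_rank,n_exposed,pct_exposed,adjusted_cost_usd,variability_index,prioritization_score
Parenteral Nutrition,pharmaceutical,1,1,14,23752,89,58411076,3.21,6.56
Anticoagulants,pharmaceutical,2,3,1,19940,75,26047954,5.83,6.00
Hematology,laboratory,3,12,3,25092,95,8187120,4.66,5.04
Glucose Monitoring,laboratory,4,15,2,22676,85,5616816,4.67,4.85
Chemistries,laboratory,5,2,17,25086,95,26914858,3.05,4.65
Intravenous Fluids and Electrolyte Replacement,pharmaceutical,6,8,6,24032,91,9719875,4.00,4.55
Blood gases,laboratory,7,4,15,22425,84,25385871,3.20,4.46
Amino acids and Metabolism,laboratory,8,24,4,13956,53,2048566,4.59,4.25
Head Ultrasounds,imaging,9,11,11,21588,81,8635416,3.57,4.07
Chest Radiographs,imaging,10,5,16,22930,86,14852629,3.09,4.04
Vitamins/Minerals/Metals,pharmaceutical,11,20,12,23583,89,3757705,3.31,4.01
Liver Function Tests,laboratory,12,25,5,13408,51,1665320,4.20,3.92
Vaccinations,pharmaceutical,13,23,7,14824,56,2110849,3.88,3.76
Abdominal Radiographs,imaging,14,13,8,15528,59,6097284,3.77,3.76
Antibiotics,pharmaceutical,15,16,20,21848,82,5181476,2.75,3.55
Bilirubin Monitoring,laboratory,16,18,28,24463,92,4546251,2.22,3.51
Hormone levels,laboratory,17,31,10,14574,55,982116,3.63,3.51
Bacteriology,laboratory,18,17,26,23362,88,4617621,2.41,3.50
Analeptic Stimulants,pharmaceutical,19,7,24,20701,78,10046125,2.54,3.41
Opioid Analgesics,pharmaceutical,20,29,9,10648,40,1079652,3.65,3.37
Blood bank testing,laboratory,21,22,23,20811,78,2384766,2.55,3.32
Lipid testing,laboratory,22,26,19,17392,66,1343400,2.81,3.15
Sedatives,pharmaceutical,23,36,13,6282,24,468759,3.29,2.88
Echocardiograms,imaging,24,6,25,10273,39,13971996,2.45,2.73
Blood Products,pharmaceutical,25,19,18,8541,32,3916533,2.89,2.69
Viral testing,laboratory,26,27,21,6970,26,1222943,2.71,2.47
Non-opioid Analgesics,pharmaceutical,27,21,22,8265,31,3203314,2.55,2.41
Surfactant Agents,pharmaceutical,28,9,33,10875,41,8794328,1.69,2.10
Immunoglobulins,pharmaceutical,29,10,35,4497,17,8674122,1.18,2.07
Diuretic agents,pharmaceutical,30,34,29,7553,28,752242,2.15,2.05
Corticosteroids,pharmaceutical,31,30,30,5050,19,1055401,2.07,1.87
Vascular Ultrasounds,imaging,32,35,31,1694,6,708383,1.97,1.70
Inhaled Bronchodilators and/or Steroids,pharmaceutical,33,33,32,2667,10,776060,1.78,1.56
Inhaled Nitric Oxide,pharmaceutical,34,14,27,1845,7,5854650,2.26,1.28
GI Fluoroscopy,imaging,35,32,34,2674,10,814412,1.23,1.10
Abdominal Ultrasounds,imaging,36,28,36,4071,15,1192815,0.86,0.89
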