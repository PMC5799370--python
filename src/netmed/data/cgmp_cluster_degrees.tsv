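# Per-layer degree centralities of the 12 diseases in the published
# cGMP-related cerebro-cardio-metabolic diseasome cluster.
disease	gene_degree	interaction_degree	symptom_degree	comorbidity_degree
Stroke	10	10	2	7
Alzheimer disease	6	9	1	5
Dementia	6	10	3	0
Atherosclerosis	3	6	0	8
Asthma	3	7	1	5
Diabetes mellitus	6	10	0	0
Parkinson disease	3	7	2	4
Heart Failure	1	4	2	7
Migraine Disorders	1	7	0	5
Myocardial Infarction	4	7	2	0
Hypertension	1	3	1	7
Obesity	2	4	0	6
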