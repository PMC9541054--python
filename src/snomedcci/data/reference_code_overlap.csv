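condition,vocabulary,both,snomed_only,quan_only
mi,ICD9CM,42,0,0
chf,ICD9CM,33,1,0
pvd,ICD9CM,48,4,1
cvd,ICD9CM,91,5,0
dementia,ICD9CM,22,4,0
chronic_pulmonary,ICD9CM,58,2,1
rheumatic,ICD9CM,14,2,1
pud,ICD9CM,112,0,0
mild_liver,ICD9CM,27,9,1
diabetes_without_cc,ICD9CM,30,7,0
diabetes_with_cc,ICD9CM,20,36,0
paralysis,ICD9CM,48,7,0
renal,ICD9CM,46,12,0
malignancy,ICD9CM,738,14,0
severe_liver,ICD9CM,9,0,0
metastatic_tumor,ICD9CM,47,7,0
aids_hiv,ICD9CM,1,0,0
mi,ICD10CM,24,2,0
chf,ICD10CM,40,1,2
pvd,ICD10CM,319,13,6
cvd,ICD10CM,531,17,0
dementia,ICD10CM,18,0,0
chronic_pulmonary,ICD10CM,85,1,1
rheumatic,ICD10CM,465,125,2
pud,ICD10CM,40,0,0
mild_liver,ICD10CM,48,12,0
diabetes_without_cc,ICD10CM,72,21,3
diabetes_with_cc,ICD10CM,270,175,0
paralysis,ICD10CM,55,11,0
renal,ICD10CM,34,18,0
malignancy,ICD10CM,1177,30,124
severe_liver,ICD10CM,21,5,0
metastatic_tumor,ICD10CM,62,12,0
aids_hiv,ICD10CM,1,0,0
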