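condition,information_gain,added_noise,deprecated_unmapped,specificity
mi,2,0,0,0
chf,0,3,0,1
pvd,15,9,0,0
cvd,22,0,0,0
dementia,4,0,0,0
chronic_pulmonary,3,2,0,0
rheumatic,9,121,0,0
pud,0,0,0,0
mild_liver,20,1,0,1
diabetes_without_cc,5,23,3,0
diabetes_with_cc,30,181,0,0
paralysis,6,12,0,0
renal,18,12,0,0
malignancy,2,36,120,10
severe_liver,2,3,0,0
metastatic_tumor,0,19,0,0
aids_hiv,0,0,0,0
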