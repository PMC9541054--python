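condition,vocabulary,code,provenance
mi,ICD9CM,410*,quan_icd9
mi,ICD9CM,412*,quan_icd9
chf,ICD9CM,398.91,quan_icd9
chf,ICD9CM,402.01,quan_icd9
chf,ICD9CM,402.11,quan_icd9
chf,ICD9CM,402.91,quan_icd9
chf,ICD9CM,404.01,quan_icd9
chf,ICD9CM,404.03,quan_icd9
chf,ICD9CM,404.11,quan_icd9
chf,ICD9CM,404.13,quan_icd9
chf,ICD9CM,404.91,quan_icd9
chf,ICD9CM,404.93,quan_icd9
chf,ICD9CM,425.4*,quan_icd9
chf,ICD9CM,425.5*,quan_icd9
chf,ICD9CM,425.6*,quan_icd9
chf,ICD9CM,425.7*,quan_icd9
chf,ICD9CM,425.8*,quan_icd9
chf,ICD9CM,425.9*,quan_icd9
chf,ICD9CM,428*,quan_icd9
pvd,ICD9CM,093.0,quan_icd9
pvd,ICD9CM,437.3,quan_icd9
pvd,ICD9CM,440*,quan_icd9
pvd,ICD9CM,441*,quan_icd9
pvd,ICD9CM,443.1*,quan_icd9
pvd,ICD9CM,443.2*,quan_icd9
pvd,ICD9CM,443.3*,quan_icd9
pvd,ICD9CM,443.4*,quan_icd9
pvd,ICD9CM,443.5*,quan_icd9
pvd,ICD9CM,443.6*,quan_icd9
pvd,ICD9CM,443.7*,quan_icd9
pvd,ICD9CM,443.8*,quan_icd9
pvd,ICD9CM,443.9*,quan_icd9
pvd,ICD9CM,447.1,quan_icd9
pvd,ICD9CM,557.1,quan_icd9
pvd,ICD9CM,557.9,quan_icd9
pvd,ICD9CM,V43.4,quan_icd9
cvd,ICD9CM,362.34,quan_icd9
cvd,ICD9CM,430*,quan_icd9
cvd,ICD9CM,431*,quan_icd9
cvd,ICD9CM,432*,quan_icd9
cvd,ICD9CM,433*,quan_icd9
cvd,ICD9CM,434*,quan_icd9
cvd,ICD9CM,435*,quan_icd9
cvd,ICD9CM,436*,quan_icd9
cvd,ICD9CM,437*,quan_icd9
cvd,ICD9CM,438*,quan_icd9
dementia,ICD9CM,290*,quan_icd9
dementia,ICD9CM,294.1*,quan_icd9
dementia,ICD9CM,331.2,quan_icd9
chronic_pulmonary,ICD9CM,416.8,quan_icd9
chronic_pulmonary,ICD9CM,416.9,quan_icd9
chronic_pulmonary,ICD9CM,490*,quan_icd9
chronic_pulmonary,ICD9CM,491*,quan_icd9
chronic_pulmonary,ICD9CM,492*,quan_icd9
chronic_pulmonary,ICD9CM,493*,quan_icd9
chronic_pulmonary,ICD9CM,494*,quan_icd9
chronic_pulmonary,ICD9CM,495*,quan_icd9
chronic_pulmonary,ICD9CM,496*,quan_icd9
chronic_pulmonary,ICD9CM,497*,quan_icd9
chronic_pulmonary,ICD9CM,498*,quan_icd9
chronic_pulmonary,ICD9CM,499*,quan_icd9
chronic_pulmonary,ICD9CM,500*,quan_icd9
chronic_pulmonary,ICD9CM,501*,quan_icd9
chronic_pulmonary,ICD9CM,502*,quan_icd9
chronic_pulmonary,ICD9CM,503*,quan_icd9
chronic_pulmonary,ICD9CM,504*,quan_icd9
chronic_pulmonary,ICD9CM,505*,quan_icd9
chronic_pulmonary,ICD9CM,506.4,quan_icd9
chronic_pulmonary,ICD9CM,508.1,quan_icd9
chronic_pulmonary,ICD9CM,508.8,quan_icd9
rheumatic,ICD9CM,446.5,quan_icd9
rheumatic,ICD9CM,710.0,quan_icd9
rheumatic,ICD9CM,710.1,quan_icd9
rheumatic,ICD9CM,710.2,quan_icd9
rheumatic,ICD9CM,710.3,quan_icd9
rheumatic,ICD9CM,710.4,quan_icd9
rheumatic,ICD9CM,714.0,quan_icd9
rheumatic,ICD9CM,714.1,quan_icd9
rheumatic,ICD9CM,714.2,quan_icd9
rheumatic,ICD9CM,714.8*,quan_icd9
rheumatic,ICD9CM,725*,quan_icd9
pud,ICD9CM,531*,quan_icd9
pud,ICD9CM,532*,quan_icd9
pud,ICD9CM,533*,quan_icd9
pud,ICD9CM,534*,quan_icd9
mild_liver,ICD9CM,070.22,quan_icd9
mild_liver,ICD9CM,070.23,quan_icd9
mild_liver,ICD9CM,070.32,quan_icd9
mild_liver,ICD9CM,070.33,quan_icd9
mild_liver,ICD9CM,070.44,quan_icd9
mild_liver,ICD9CM,070.54,quan_icd9
mild_liver,ICD9CM,070.6,quan_icd9
mild_liver,ICD9CM,070.9,quan_icd9
mild_liver,ICD9CM,570*,quan_icd9
mild_liver,ICD9CM,571*,quan_icd9
mild_liver,ICD9CM,573.3,quan_icd9
mild_liver,ICD9CM,573.4,quan_icd9
mild_liver,ICD9CM,573.8,quan_icd9
mild_liver,ICD9CM,573.9,quan_icd9
mild_liver,ICD9CM,V42.7,quan_icd9
diabetes_without_cc,ICD9CM,250.0*,quan_icd9
diabetes_without_cc,ICD9CM,250.1*,quan_icd9
diabetes_without_cc,ICD9CM,250.2*,quan_icd9
diabetes_without_cc,ICD9CM,250.3*,quan_icd9
diabetes_without_cc,ICD9CM,250.8*,quan_icd9
diabetes_without_cc,ICD9CM,250.9*,quan_icd9
diabetes_with_cc,ICD9CM,250.4*,quan_icd9
diabetes_with_cc,ICD9CM,250.5*,quan_icd9
diabetes_with_cc,ICD9CM,250.6*,quan_icd9
diabetes_with_cc,ICD9CM,250.7*,quan_icd9
paralysis,ICD9CM,334.1,quan_icd9
paralysis,ICD9CM,342*,quan_icd9
paralysis,ICD9CM,343*,quan_icd9
paralysis,ICD9CM,344.0*,quan_icd9
paralysis,ICD9CM,344.1,quan_icd9
paralysis,ICD9CM,344.2,quan_icd9
paralysis,ICD9CM,344.3,quan_icd9
paralysis,ICD9CM,344.4*,quan_icd9
paralysis,ICD9CM,344.5,quan_icd9
paralysis,ICD9CM,344.6*,quan_icd9
paralysis,ICD9CM,344.9,quan_icd9
renal,ICD9CM,403.01,quan_icd9
renal,ICD9CM,403.11,quan_icd9
renal,ICD9CM,403.91,quan_icd9
renal,ICD9CM,404.02,quan_icd9
renal,ICD9CM,404.03,quan_icd9
renal,ICD9CM,404.12,quan_icd9
renal,ICD9CM,404.13,quan_icd9
renal,ICD9CM,404.92,quan_icd9
renal,ICD9CM,404.93,quan_icd9
renal,ICD9CM,582*,quan_icd9
renal,ICD9CM,583.0,quan_icd9
renal,ICD9CM,583.1,quan_icd9
renal,ICD9CM,583.2,quan_icd9
renal,ICD9CM,583.4,quan_icd9
renal,ICD9CM,583.6,quan_icd9
renal,ICD9CM,583.7,quan_icd9
renal,ICD9CM,585*,quan_icd9
renal,ICD9CM,586*,quan_icd9
renal,ICD9CM,588.0,quan_icd9
renal,ICD9CM,V42.0,quan_icd9
renal,ICD9CM,V45.1,quan_icd9
renal,ICD9CM,V56*,quan_icd9
malignancy,ICD9CM,140*,quan_icd9
malignancy,ICD9CM,141*,quan_icd9
malignancy,ICD9CM,142*,quan_icd9
malignancy,ICD9CM,143*,quan_icd9
malignancy,ICD9CM,144*,quan_icd9
malignancy,ICD9CM,145*,quan_icd9
malignancy,ICD9CM,146*,quan_icd9
malignancy,ICD9CM,147*,quan_icd9
malignancy,ICD9CM,148*,quan_icd9
malignancy,ICD9CM,149*,quan_icd9
malignancy,ICD9CM,150*,quan_icd9
malignancy,ICD9CM,151*,quan_icd9
malignancy,ICD9CM,152*,quan_icd9
malignancy,ICD9CM,153*,quan_icd9
malignancy,ICD9CM,154*,quan_icd9
malignancy,ICD9CM,155*,quan_icd9
malignancy,ICD9CM,156*,quan_icd9
malignancy,ICD9CM,157*,quan_icd9
malignancy,ICD9CM,158*,quan_icd9
malignancy,ICD9CM,159*,quan_icd9
malignancy,ICD9CM,160*,quan_icd9
malignancy,ICD9CM,161*,quan_icd9
malignancy,ICD9CM,162*,quan_icd9
malignancy,ICD9CM,163*,quan_icd9
malignancy,ICD9CM,164*,quan_icd9
malignancy,ICD9CM,165*,quan_icd9
malignancy,ICD9CM,166*,quan_icd9
malignancy,ICD9CM,167*,quan_icd9
malignancy,ICD9CM,168*,quan_icd9
malignancy,ICD9CM,169*,quan_icd9
malignancy,ICD9CM,170*,quan_icd9
malignancy,ICD9CM,171*,quan_icd9
malignancy,ICD9CM,172*,quan_icd9
malignancy,ICD9CM,174*,quan_icd9
malignancy,ICD9CM,175*,quan_icd9
malignancy,ICD9CM,176*,quan_icd9
malignancy,ICD9CM,177*,quan_icd9
malignancy,ICD9CM,178*,quan_icd9
malignancy,ICD9CM,179*,quan_icd9
malignancy,ICD9CM,180*,quan_icd9
malignancy,ICD9CM,181*,quan_icd9
malignancy,ICD9CM,182*,quan_icd9
malignancy,ICD9CM,183*,quan_icd9
malignancy,ICD9CM,184*,quan_icd9
malignancy,ICD9CM,185*,quan_icd9
malignancy,ICD9CM,186*,quan_icd9
malignancy,ICD9CM,187*,quan_icd9
malignancy,ICD9CM,188*,quan_icd9
malignancy,ICD9CM,189*,quan_icd9
malignancy,ICD9CM,190*,quan_icd9
malignancy,ICD9CM,191*,quan_icd9
malignancy,ICD9CM,192*,quan_icd9
malignancy,ICD9CM,193*,quan_icd9
malignancy,ICD9CM,194*,quan_icd9
malignancy,ICD9CM,195.0,quan_icd9
malignancy,ICD9CM,195.1,quan_icd9
malignancy,ICD9CM,195.2,quan_icd9
malignancy,ICD9CM,195.3,quan_icd9
malignancy,ICD9CM,195.4,quan_icd9
malignancy,ICD9CM,195.5,quan_icd9
malignancy,ICD9CM,195.8,quan_icd9
malignancy,ICD9CM,200*,quan_icd9
malignancy,ICD9CM,201*,quan_icd9
malignancy,ICD9CM,202*,quan_icd9
malignancy,ICD9CM,203*,quan_icd9
malignancy,ICD9CM,204*,quan_icd9
malignancy,ICD9CM,205*,quan_icd9
malignancy,ICD9CM,206*,quan_icd9
malignancy,ICD9CM,207*,quan_icd9
malignancy,ICD9CM,208*,quan_icd9
malignancy,ICD9CM,238.6,quan_icd9
severe_liver,ICD9CM,456.0,quan_icd9
severe_liver,ICD9CM,456.1,quan_icd9
severe_liver,ICD9CM,456.2*,quan_icd9
severe_liver,ICD9CM,572.2,quan_icd9
severe_liver,ICD9CM,572.3,quan_icd9
severe_liver,ICD9CM,572.4,quan_icd9
severe_liver,ICD9CM,572.8,quan_icd9
metastatic_tumor,ICD9CM,196*,quan_icd9
metastatic_tumor,ICD9CM,197*,quan_icd9
metastatic_tumor,ICD9CM,198*,quan_icd9
metastatic_tumor,ICD9CM,199*,quan_icd9
aids_hiv,ICD9CM,042*,quan_icd9
aids_hiv,ICD9CM,043*,quan_icd9
aids_hiv,ICD9CM,044*,quan_icd9
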