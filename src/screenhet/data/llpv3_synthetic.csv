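# SYNTHETIC stand-in coefficient table in the functional form of the
# Liverpool Lung Project (LLP) risk model family (age, sex, smoking
# duration category, prior pneumonia, asbestos exposure, prior malignancy,
# family history of lung cancer).  The published LLPv3 coefficients are NOT
# reproduced here; these values are plausible placeholders for exercising
# the scoring, quintile and two-stage machinery.  Do not use for clinical
# risk estimation.
term,level,coefficient,centering
intercept,,-6.90,
age,,0.045,60
sex,male,0.25,
smoking_duration_cat,1-20,0.30,
smoking_duration_cat,21-40,0.80,
smoking_duration_cat,>40,1.10,
pneumonia,,0.35,
asbestos,,0.30,
personal_cancer_history,,0.45,
family_lc_history,,0.50,
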