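# PLCOm2012 6-year lung-cancer risk model for ever-smokers.
# Source: Tammemagi MC et al., Selection criteria for lung-cancer screening,
# N Engl J Med 2013;368:728-736 (model coefficient table).
# Continuous terms are centered at the listed value before multiplication;
# smoking intensity enters as (cigs_per_day/10)^-1 centered as listed.
term,level,coefficient,centering
intercept,,-4.532506,
age,,0.0778868,62
race_ethnicity,black,0.3944778,
race_ethnicity,hispanic,-0.7434744,
race_ethnicity,asian,-0.466585,
education,,-0.0812744,4
bmi,,-0.0274194,27
copd,,0.3553063,
personal_cancer_history,,0.4589971,
family_lc_history,,0.587185,
smoking_status,current,0.2597431,
smoking_intensity_inv,,-1.822606,0.4021541613
years_smoked,,0.0317321,27
years_quit,,-0.0308572,10
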