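variable,label,labelLong,subject,section,variableType,units,notes
DHH_SEX,Sex,Sex of respondent,Demographics,socio-demographic,Categorical,N/A,
DHHGAGE,Age group,"Age group of respondent, harmonized",Age,socio-demographic,Categorical,N/A,Source cycles use 15 (2001/2003) or 16 (2005 onward) categories; the 15-17 and 18-19 groups are collapsed to 15-19.
DHHGAGE_cont,Age (continuous),Continuous age from age-group midpoints,Age,socio-demographic,Continuous,years,Midpoint of each age group; the open-ended 80+ group maps to 85.
DHHGMS,Marital status,Marital status of respondent,Demographics,socio-demographic,Categorical,N/A,
INCGHH,Household income group,Total household income group,Income,socio-demographic,Categorical,N/A,
HWTGHTM,Height,Self-reported height,Body weight,health status,Continuous,m,
HWTGWTK,Weight,Self-reported weight,Body weight,health status,Continuous,kg,
HWTGBMI,BMI (original),Body mass index as shipped in each cycle,Body weight,health status,Continuous,kg/m2,Cycles differ in rounding (1 vs 2 decimals) and in age and height/weight restrictions; prefer HWTGBMI_der for cross-cycle use.
HWTGBMI_der,BMI (derived),Body mass index recomputed from height and weight,Body weight,health status,Continuous,kg/m2,"Computed uniformly for all respondents regardless of age, removing cycle-specific restrictions."
SMKDSTY_A,Smoking status,Type of smoker,Smoking,health behaviours,Categorical,N/A,
SMK_204_cont,Cigarettes per day,Number of cigarettes smoked per day,Smoking,health behaviours,Continuous,cigarettes/day,
SMKG040_cont,Age started smoking,Age started smoking daily,Smoking,health behaviours,Continuous,years,
SMKG852_cont,Age quit smoking,Age stopped smoking daily (former smokers),Smoking,health behaviours,Continuous,years,
pack_years_der,Smoking pack-years,Cumulative smoking exposure in pack-years,Smoking,health behaviours,Continuous,pack-years,(cigarettes per day / 20) x years smoked; never-smokers score 0.
ALW_5PL,Frequency of 5+ drinks,Frequency of consuming 5 or more drinks on one occasion,Alcohol,health behaviours,Categorical,N/A,Not collected in the 2001 cycle.
binge_drinker_der,Binge drinker,5+ drinks on one occasion at least monthly,Alcohol,health behaviours,Categorical,N/A,
ADL_01,ADL: meal preparation,Needs help preparing meals,Activities of daily living,health status,Categorical,N/A,
ADL_02,ADL: errands,Needs help getting to appointments or running errands,Activities of daily living,health status,Categorical,N/A,
ADL_03,ADL: housework,Needs help doing housework,Activities of daily living,health status,Categorical,N/A,
ADL_04,ADL: personal care,Needs help with personal care,Activities of daily living,health status,Categorical,N/A,
ADL_05,ADL: moving inside house,Needs help moving about inside the house,Activities of daily living,health status,Categorical,N/A,
ADL_score_5,ADL score (0-5),Number of the five ADL items requiring assistance,Activities of daily living,health status,Continuous,count,
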