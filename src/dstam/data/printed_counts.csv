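attribute,category,total,covered_july,covered_november
overall,all,2258823,1017011,1574724
stratum_group,Low,1109549,221296,568115
stratum_group,Middle,935699,645076,841224
stratum_group,High,204589,147229,160082
stratum_group,N.D.,8986,3410,5303
ethnicity,Afrodescendent,325865,85481,174224
ethnicity,Rrom,102,40,58
ethnicity,Indigenous,11112,4339,7394
ethnicity,Islander/Raizal,382,214,276
ethnicity,Other,1890491,910535,1369069
ethnicity,Palenque,245,41,231
ethnicity,N.D.,30626,16361,23472
education,Graduate degree,72441,48919,57641
education,Bachelor's degree,295319,187250,240652
education,Technical,244160,123846,187591
education,Middle,608429,254015,409594
education,High School,337065,132875,222293
education,Primary,468206,178303,304450
education,Pre-school,36294,13559,23360
education,No data,196909,78244,129143
literacy,Literate,2043041,935369,1436134
literacy,No literacy,66383,21864,40417
literacy,N.A.,121140,44609,76938
literacy,N.D.,28259,15169,21235
sex,Fem,1208617,547601,844077
sex,Masc,1050206,469410,730647
civil_status,Single,821536,370444,575999
civil_status,Married or cohabitation,896958,403517,624355
civil_status,Divorced or separated,163980,81711,118628
civil_status,Widow,95611,52705,73457
civil_status,N.A.,254492,94566,162468
civil_status,N.D.,26246,14068,19817
age_band,0-4,121140,44609,76938
age_band,0-14,400527,150093,256909
age_band,5-14,279387,105484,179971
age_band,15-24,363311,147838,242147
age_band,15-59,1482069,657107,1027559
age_band,15-64,1595016,716344,1111425
age_band,60+,376227,209811,290256
age_band,65+,263280,150574,206390
age_band,80+,64100,40103,52080
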