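study_id,year,country,ethnicity,cancer_type,snp_id,effect_allele,case_g0,case_g1,case_g2,ctrl_g0,ctrl_g1,ctrl_g2,case_exposed,case_unexposed,ctrl_exposed,ctrl_unexposed,collapsed_model
Gansmo2015-Colon,2015,Norway,Caucasian,Colon cancer,rs4245739,C,823,600,108,2042,1439,266,,,,,
Gansmo2015-Lung,2015,Norway,Caucasian,Lung cancer,rs4245739,C,715,515,101,2042,1439,266,,,,,
Gansmo2015-Prostate,2015,Norway,Caucasian,Prostate cancer,rs4245739,C,1412,927,161,2042,1439,266,,,,,
Gansmo2015-Breast,2015,Norway,Caucasian,Breast cancer,rs4245739,C,966,643,108,2042,1439,266,,,,,
Gao2015a,2015,China,Asian,SCLC,rs4245739,C,297,22,1,548,90,2,,,,,
Gao2015b,2015,China,Asian,SCLC,rs4245739,C,183,17,0,321,77,2,,,,,
Fan2014,2014,China,Asian,NHL,rs4245739,C,187,13,0,346,53,1,,,,,
Liu2013a,2013,China,Asian,Breast cancer,rs4245739,C,733,67,0,686,111,3,,,,,
Liu2013b,2013,China,Asian,Breast cancer,rs4245739,C,278,22,0,501,96,3,,,,,
Zhou2013a,2013,China,Asian,ESCC,rs4245739,C,501,37,2,478,70,2,,,,,
Zhou2013b,2013,China,Asian,ESCC,rs4245739,C,529,56,3,510,88,2,,,,,
Garcia-Closas2013,2013,Mixed,Caucasian,Breast cancer,rs4245739,C,3318,2637,557,22825,15798,2828,,,,,
Zhang2012,2012,China,Asian,NPC,rs1563828,T,98,91,21,90,88,22,,,,,
Song2012,2012,China,Asian,Breast cancer,rs1563828,T,53,57,14,44,43,14,,,,,
Wang2012,2012,America,Caucasian,Oral cancer,rs11801299,A,195,NA,NA,201,NA,NA,,,,,
Yu2011,2011,America,Caucasian,SCCHN,rs11801299,A,684,351,40,665,376,38,,,,,
Wang2012,2012,America,Caucasian,Oral cancer,rs10900598,T,107,NA,NA,94,NA,NA,,,,,
Yu2011,2011,America,Caucasian,SCCHN,rs10900598,T,307,545,223,296,552,231,,,,,
Wu2015,2015,China,Asian,Gastric cancer,rs1380576,G,188,281,173,212,290,218,,,,,
Wang2012,2012,America,Caucasian,Oral cancer,rs1380576,G,141,NA,NA,149,NA,NA,,,,,
Yu2011,2011,America,Caucasian,SCCHN,rs1380576,G,487,477,111,518,455,106,,,,,
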