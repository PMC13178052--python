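stream,label,year,mean_age,sd_age,n_male,pct_male,n
AMBULATORY,DIAGNOSED,2018,57.25,21.35,32674,45.19,72309
AMBULATORY,DIAGNOSED,2019,57.83,21.33,35637,46.02,77445
AMBULATORY,DIAGNOSED,2020,59.86,19.75,30663,47.98,63905
AMBULATORY,DIAGNOSED,2021,60.26,19.16,44431,48.91,90842
AMBULATORY,DIAGNOSED,2022,61.15,18.18,62291,50.58,123155
AMBULATORY,POTENTIAL,2018,61.02,14.55,26462,53.74,49242
AMBULATORY,POTENTIAL,2019,61.94,14.06,28810,54.71,52659
AMBULATORY,POTENTIAL,2020,62.45,13.41,23556,55.29,42603
AMBULATORY,POTENTIAL,2021,62.48,13.96,28139,55.19,50986
AMBULATORY,POTENTIAL,2022,62.66,14.49,28136,54.79,51351
MORTALITY,DIAGNOSED,2018,74.68,17.42,53239,49.10,108430
MORTALITY,DIAGNOSED,2019,74.88,17.14,53935,49.14,109758
MORTALITY,DIAGNOSED,2020,74.79,15.98,58719,49.83,117849
MORTALITY,DIAGNOSED,2021,74.88,16.02,65535,49.65,131981
MORTALITY,DIAGNOSED,2022,75.36,16.41,64342,48.96,131411
MORTALITY,POTENTIAL,2018,70.75,21.57,105724,56.28,187856
MORTALITY,POTENTIAL,2019,70.97,21.16,107688,56.20,191612
MORTALITY,POTENTIAL,2020,71.30,19.20,110659,57.01,194111
MORTALITY,POTENTIAL,2021,71.12,19.07,120797,56.55,213606
MORTALITY,POTENTIAL,2022,71.47,19.52,113179,56.19,201418
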