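site,year,total,adult,juvenile,seedling
TNFP1,2019,<200,—,—,—
TNFP1,2021,16,0,15,1
TNFP1,2022,15,3,12,0
TNFP2,2021,204,63,122,19
TNFP2,2022,173,65,90,18
ZEFR1,2021,24,5,19,0
ZEFR1,2022,14,3,11,0
ZEFR2,2022,274,36,233,5
TGM,2019,<200,—,—,—
TGM,2021,15,4,11,0
TGM,2022,30,11,19,0
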