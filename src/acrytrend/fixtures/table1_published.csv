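study_id,country,region,year_start,year_end,matrix,smoking,analyte,n,mean,median,q1,q3,min,max,sd,lod,lod_unknown,unit,mean_age,pct_male,source,excluded_flag,exclusion_reason
LH,SE,north,1991,1996,blood,nonsmoker,AAVal,70,,31,,,,,,,,pmol_per_g_Hb,,,published,True,multi-year sampling window 1991-1996 without yearly means
LH,SE,north,1991,1996,blood,smoker,AAVal,72,,152,,,,,,,,pmol_per_g_Hb,,,published,True,multi-year sampling window 1991-1996 without yearly means
MOS,ES,south,1992,2000,blood,nonsmoker,AAVal,417,,43.1,,,,,,,,pmol_per_g_Hb,58,0,published,True,multi-year sampling window 1992-2000 without yearly means
MOS,ES,south,1992,2000,blood,nonsmoker,GAVal,417,,35.4,,,,,,,,pmol_per_g_Hb,58,0,published,True,multi-year sampling window 1992-2000 without yearly means
AV1,SE,north,1999,2000,blood,nonsmoker,AAVal,68,,39,,,,,,,,pmol_per_g_Hb,,,published,True,multi-year sampling window 1999-2000 without yearly means
AV1,SE,north,1999,2000,blood,nonsmoker,GAVal,68,,67,,,,,,,,pmol_per_g_Hb,,,published,True,multi-year sampling window 1999-2000 without yearly means
TS1,DE,central_west,2001,2001,blood,nonsmoker,AAVal,25,,21,,,,,,,,pmol_per_g_Hb,34,88,published,,
TS1,DE,central_west,2001,2001,blood,smoker,AAVal,47,,85,,,,,,,,pmol_per_g_Hb,34,88,published,,
MU,DE,central_west,2002,2002,urine_24h,nonsmoker,AAMA,60,41.6,,,,,,,,,ug_per_L,,38.3,published,True,dual-matrix validation study marked excluded in source overview
MU,DE,central_west,2002,2002,urine_24h,nonsmoker,GAMA,60,8.7,,,,,,,,,ug_per_L,,38.3,published,True,dual-matrix validation study marked excluded in source overview
MU,DE,central_west,2002,2002,urine_24h,smoker,AAMA,60,107.3,,,,,,,,,ug_per_L,,38.3,published,True,dual-matrix validation study marked excluded in source overview
MU,DE,central_west,2002,2002,urine_24h,smoker,GAMA,60,15.0,,,,,,,,,ug_per_L,,38.3,published,True,dual-matrix validation study marked excluded in source overview
MU,DE,central_west,2002,2002,blood,nonsmoker,AAVal,60,27.6,,,,,,,,,pmol_per_g_Hb,,38.3,published,True,dual-matrix validation study marked excluded in source overview
MU,DE,central_west,2002,2002,blood,smoker,AAVal,60,81.8,,,,,,,,,pmol_per_g_Hb,,38.3,published,True,dual-matrix validation study marked excluded in source overview
SC,FR,central_west,,,blood,nonsmoker,AAVal,52,2753,,,,,,,,,pmol_per_L,,42.6,published,True,no sampling year reported
SC,FR,central_west,,,blood,nonsmoker,GAVal,52,2334,,,,,,,,,pmol_per_L,,42.6,published,True,no sampling year reported
TS2,DE,central_west,2003,2003,blood,nonsmoker,AAVal,13,18,,,,,,,,,pmol_per_g_Hb,35,23.0,published,,
TS2,DE,central_west,2003,2003,blood,nonsmoker,GAVal,13,17,,,,,,,,,pmol_per_g_Hb,35,23.0,published,,
TS2,DE,central_west,2003,2003,blood,smoker,AAVal,16,80,,,,,,,,,pmol_per_g_Hb,35,23.0,published,,
TS2,DE,central_west,2003,2003,blood,smoker,GAVal,16,53,,,,,,,,,pmol_per_g_Hb,35,23.0,published,,
BK,DE,central_west,2003,2003,blood,nonsmoker,AAVal,857,28.2,,,,,,,,,pmol_per_g_Hb,41.6,46.9,published,,
BK,DE,central_west,2003,2003,blood,smoker,AAVal,148,82.6,,,,,,,,,pmol_per_g_Hb,41.6,46.9,published,,
MB,DE,central_west,2003,2003,spot_urine,nonsmoker,AAMA,16,,29,,,,,,,,ug_per_L,25.5,31.2,published,,
MB,DE,central_west,2003,2003,spot_urine,nonsmoker,GAMA,16,,5,,,,,,,,ug_per_L,25.5,31.2,published,,
MB,DE,central_west,2003,2003,spot_urine,smoker,AAMA,13,,127,,,,,,,,ug_per_L,25.5,31.2,published,,
MB,DE,central_west,2003,2003,spot_urine,smoker,GAMA,13,,19,,,,,,,,ug_per_L,25.5,31.2,published,,
TS3,DE,central_west,2003,2003,blood,nonsmoker,AAVal,92,,29.9,,,,,,,,pmol_per_g_Hb,35,21.7,published,,
TS3,DE,central_west,2003,2003,blood,nonsmoker,GAVal,92,,35.2,,,,,,,,pmol_per_g_Hb,35,21.7,published,,
EH,DE,central_west,2003,2003,spot_urine,nonsmoker,AAMA,91,,29,,,,229,,,True,ug_per_L,36,49.4,published,,
EH,DE,central_west,2003,2003,spot_urine,nonsmoker,GAMA,91,,7,,,,,,,,ug_per_L,36,49.4,published,,
EH,DE,central_west,2003,2003,blood,nonsmoker,AAVal,91,,30,,,15,71,,,,pmol_per_g_Hb,36,49.4,published,,
EH,DE,central_west,2003,2003,blood,nonsmoker,GAVal,91,,34,,,,,,,,pmol_per_g_Hb,36,49.4,published,,
TB,NO,north,2005,2005,blood,nonsmoker,AAVal,44,38.4,,,,,,,,,pmol_per_g_Hb,45,45.4,published,,
TB,NO,north,2005,2005,blood,nonsmoker,GAVal,44,19.6,,,,,,,,,pmol_per_g_Hb,45,45.4,published,,
TB,NO,north,2005,2005,blood,smoker,AAVal,6,154,,,,,,,,,pmol_per_g_Hb,45,45.4,published,,
TB,NO,north,2005,2005,blood,smoker,GAVal,6,76.6,,,,,,,,,pmol_per_g_Hb,45,45.4,published,,
UH,DE,central_west,2007,2007,spot_urine,nonsmoker,AAMA,110,57.8,,,,,,,,,ug_per_L,5.5,57.2,published,,
UH,DE,central_west,2007,2007,spot_urine,nonsmoker,GAMA,110,18.3,,,,,,,,,ug_per_L,5.5,57.2,published,,
HS,SE,north,2007,2007,blood,nonsmoker,AAVal,81,28,,,,,,,,,pmol_per_g_Hb,30,0,published,,
HS,SE,north,2007,2007,blood,nonsmoker,GAVal,81,22,,,,,,,,,pmol_per_g_Hb,30,0,published,,
HS,SE,north,2007,2007,blood,smoker,AAVal,6,110,,,,,,,,,pmol_per_g_Hb,30,0,published,,
HS,SE,north,2007,2007,blood,smoker,GAVal,6,102,,,,,,,,,pmol_per_g_Hb,30,0,published,,
EKK,DE,central_west,2008,2008,spot_urine,nonsmoker,AAMA,67,,39,,,,,,,,ug_per_L,35.5,32.8,published,,
EKK,DE,central_west,2008,2008,spot_urine,nonsmoker,GAMA,67,,9,,,,,,,,ug_per_L,35.5,32.8,published,,
EKK,DE,central_west,2008,2008,spot_urine,smoker,AAMA,67,,121,,,,,,,,ug_per_L,35.5,32.8,published,,
EKK,DE,central_west,2008,2008,spot_urine,smoker,GAMA,67,,25,,,,,,,,ug_per_L,35.5,32.8,published,,
TDS,NO,north,2007,2009,blood,nonsmoker,AAVal,79,31,,,,,,,,,pmol_per_g_Hb,30,0,published,,
TDS,NO,north,2007,2009,blood,nonsmoker,GAVal,79,23,,,,,,,,,pmol_per_g_Hb,30,0,published,,
AV2,SE,north,2011,2011,blood,nonsmoker,AAVal,10,59,,,,,,,,,pmol_per_g_Hb,46,50,published,,
AV2,SE,north,2011,2011,blood,nonsmoker,GAVal,10,72,,,,,,,,,pmol_per_g_Hb,46,50,published,,
HM,PL,central_west,2012,2012,spot_urine,nonsmoker,AAMA,78,,18.9,,,,,,,,ug_per_L,30,0,published,,
HM,PL,central_west,2012,2012,spot_urine,nonsmoker,GAMA,78,,6.8,,,,,,,,ug_per_L,30,0,published,,
HM,PL,central_west,2012,2012,spot_urine,smoker,AAMA,5,,168,,,,,,,,ug_per_L,30,0,published,,
HM,PL,central_west,2012,2012,spot_urine,smoker,GAMA,5,,27.7,,,,,,,,ug_per_L,30,0,published,,
KG,DE,central_west,2015,2015,urine_12h,nonsmoker,AAMA,20,312,,,,,,,,,nmol_per_day,26,50,published,,
KG,DE,central_west,2015,2015,urine_12h,nonsmoker,GAMA,20,45,,,,,,,,,nmol_per_day,26,50,published,,
KG2,DE,central_west,2015,2015,blood,nonsmoker,AAVal,6,24.5,,,,,,,,,pmol_per_g_Hb,32,100,published,,
KG2,DE,central_west,2015,2015,blood,nonsmoker,GAVal,6,17.2,,,,,,,,,pmol_per_g_Hb,32,100,published,,
GF,IT,south,2017,2017,urine_24h,nonsmoker,AAMA,38,,142,,,,,,,,ug_per_g_creatinine,46,89.4,published,True,24 h urine with creatinine-based unit marked excluded in source overview
GF,IT,south,2017,2017,urine_24h,nonsmoker,GAMA,38,,1.3,,,,,,,,ug_per_g_creatinine,46,89.4,published,True,24 h urine with creatinine-based unit marked excluded in source overview
GF,IT,south,2017,2017,urine_24h,smoker,AAMA,22,,405,,,,,,,,ug_per_g_creatinine,46,89.4,published,True,24 h urine with creatinine-based unit marked excluded in source overview
GF,IT,south,2017,2017,urine_24h,smoker,GAMA,22,,3.2,,,,,,,,ug_per_g_creatinine,46,89.4,published,True,24 h urine with creatinine-based unit marked excluded in source overview
GS,DE,central_west,2015,2017,spot_urine,nonsmoker,AAMA,2211,95.33,,,,,,,,,ug_per_L,10.4,51.6,published,True,overlaps the GerES V aligned dataset
GS,DE,central_west,2015,2017,spot_urine,smoker,AAMA,48,242.4,,,,,,,,,ug_per_L,10.4,51.6,published,True,overlaps the GerES V aligned dataset
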