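study_id,country,region,year_start,year_end,matrix,smoking,analyte,n,mean,median,q1,q3,min,max,sd,lod,lod_unknown,unit,mean_age,pct_male,source,excluded_flag,exclusion_reason
IT1,IT,south,2014,2014,spot_urine,nonsmoker,AAMA,18,64.85,,,,,,,,,ug_per_L,7.0,0,aligned,,
IT1,IT,south,2014,2014,spot_urine,nonsmoker,GAMA,18,24.73,,,,,,,,,ug_per_L,7.0,0,aligned,,
IT2,IT,south,2015,2015,spot_urine,nonsmoker,AAMA,132,84.58,,,,,,,,,ug_per_L,7.2,52.3,aligned,,
IT2,IT,south,2015,2015,spot_urine,nonsmoker,GAMA,132,31.57,,,,,,,,,ug_per_L,7.2,52.3,aligned,,
IT3,IT,south,2016,2016,spot_urine,nonsmoker,AAMA,147,94.58,,,,,,,,,ug_per_L,7.0,55.1,aligned,,
IT3,IT,south,2016,2016,spot_urine,nonsmoker,GAMA,147,30.46,,,,,,,,,ug_per_L,7.0,55.1,aligned,,
DE1,DE,central_west,2015,2015,spot_urine,nonsmoker,AAMA,852,90.7,,,,,,,,,ug_per_L,10.3,50.2,aligned,,
DE1,DE,central_west,2015,2015,spot_urine,nonsmoker,GAMA,852,17.57,,,,,,,,,ug_per_L,10.3,50.2,aligned,,
DE2,DE,central_west,2016,2016,spot_urine,nonsmoker,AAMA,849,88.24,,,,,,,,,ug_per_L,10.3,47.1,aligned,,
DE2,DE,central_west,2016,2016,spot_urine,nonsmoker,GAMA,849,16.43,,,,,,,,,ug_per_L,10.3,47.1,aligned,,
DE3,DE,central_west,2017,2017,spot_urine,nonsmoker,AAMA,517,102.52,,,,,,,,,ug_per_L,10.3,49.7,aligned,,
DE3,DE,central_west,2017,2017,spot_urine,nonsmoker,GAMA,517,20.52,,,,,,,,,ug_per_L,10.3,49.7,aligned,,
NO,NO,north,2016,2016,spot_urine,nonsmoker,AAMA,289,75.92,,,,,,,,,ug_per_L,9.8,52.9,aligned,,
NO,NO,north,2016,2016,spot_urine,nonsmoker,GAMA,289,11.13,,,,,,,,,ug_per_L,9.8,52.9,aligned,,
FR4,FR,central_west,2014,2014,spot_urine,nonsmoker,AAMA,55,92.6,,,,,,,,,ug_per_L,8.5,49.1,aligned,,
FR4,FR,central_west,2014,2014,spot_urine,nonsmoker,GAMA,55,12.15,,,,,,,,,ug_per_L,8.5,49.1,aligned,,
FR5,FR,central_west,2015,2015,spot_urine,nonsmoker,AAMA,208,85.52,,,,,,,,,ug_per_L,8.9,52.6,aligned,,
FR5,FR,central_west,2015,2015,spot_urine,nonsmoker,GAMA,208,11.37,,,,,,,,,ug_per_L,8.9,52.6,aligned,,
FR6,FR,central_west,2016,2016,spot_urine,nonsmoker,AAMA,37,82.97,,,,,,,,,ug_per_L,8.9,54.0,aligned,,
FR6,FR,central_west,2016,2016,spot_urine,nonsmoker,GAMA,37,11.59,,,,,,,,,ug_per_L,8.9,54.0,aligned,,
IS1,IS,north,2019,2019,spot_urine,nonsmoker,AAMA,289,70.88,,,,,,,,,ug_per_L,31.6,53.6,aligned,,
IS1,IS,north,2019,2019,spot_urine,nonsmoker,GAMA,289,9.87,,,,,,,,,ug_per_L,31.6,53.6,aligned,,
IS1,IS,north,2019,2019,spot_urine,smoker,AAMA,6,146.91,,,,,,,,,ug_per_L,31.6,53.6,aligned,,
IS1,IS,north,2019,2019,spot_urine,smoker,GAMA,6,19.24,,,,,,,,,ug_per_L,31.6,53.6,aligned,,
IS2,IS,north,2020,2020,spot_urine,nonsmoker,AAMA,154,77.57,,,,,,,,,ug_per_L,30.6,41.5,aligned,,
IS2,IS,north,2020,2020,spot_urine,nonsmoker,GAMA,154,12.18,,,,,,,,,ug_per_L,30.6,41.5,aligned,,
IS2,IS,north,2020,2020,spot_urine,smoker,AAMA,12,158.40,,,,,,,,,ug_per_L,30.6,41.5,aligned,,
IS2,IS,north,2020,2020,spot_urine,smoker,GAMA,12,22.89,,,,,,,,,ug_per_L,30.6,41.5,aligned,,
PT1,PT,south,2019,2019,spot_urine,nonsmoker,AAMA,177,84.32,,,,,,,,,ug_per_L,34.5,39.0,aligned,,
PT1,PT,south,2019,2019,spot_urine,nonsmoker,GAMA,177,29.07,,,,,,,,,ug_per_L,34.5,39.0,aligned,,
PT1,PT,south,2019,2019,spot_urine,smoker,AAMA,67,232.46,,,,,,,,,ug_per_L,34.5,39.0,aligned,,
PT1,PT,south,2019,2019,spot_urine,smoker,GAMA,67,52.07,,,,,,,,,ug_per_L,34.5,39.0,aligned,,
PT2,PT,south,2020,2020,spot_urine,nonsmoker,AAMA,37,90.85,,,,,,,,,ug_per_L,34.7,40.5,aligned,,
PT2,PT,south,2020,2020,spot_urine,nonsmoker,GAMA,37,27.96,,,,,,,,,ug_per_L,34.7,40.5,aligned,,
PT2,PT,south,2020,2020,spot_urine,smoker,AAMA,12,136.95,,,,,,,,,ug_per_L,34.7,40.5,aligned,,
PT2,PT,south,2020,2020,spot_urine,smoker,GAMA,12,50.62,,,,,,,,,ug_per_L,34.7,40.5,aligned,,
LU1,LU,central_west,2016,2016,spot_urine,nonsmoker,AAMA,34,72.48,,,,,,,,,ug_per_L,33.3,41.2,aligned,,
LU1,LU,central_west,2016,2016,spot_urine,nonsmoker,GAMA,34,13.32,,,,,,,,,ug_per_L,33.3,41.2,aligned,,
LU1,LU,central_west,2016,2016,spot_urine,smoker,AAMA,7,263.24,,,,,,,,,ug_per_L,33.3,41.2,aligned,,
LU1,LU,central_west,2016,2016,spot_urine,smoker,GAMA,7,34.71,,,,,,,,,ug_per_L,33.3,41.2,aligned,,
LU2,LU,central_west,2017,2017,spot_urine,nonsmoker,AAMA,123,68.42,,,,,,,,,ug_per_L,33.5,48.0,aligned,,
LU2,LU,central_west,2017,2017,spot_urine,nonsmoker,GAMA,123,14.44,,,,,,,,,ug_per_L,33.5,48.0,aligned,,
LU2,LU,central_west,2017,2017,spot_urine,smoker,AAMA,25,184.85,,,,,,,,,ug_per_L,33.5,48.0,aligned,,
LU2,LU,central_west,2017,2017,spot_urine,smoker,GAMA,25,28.47,,,,,,,,,ug_per_L,33.5,48.0,aligned,,
LU3,LU,central_west,2018,2018,spot_urine,nonsmoker,AAMA,12,57.93,,,,,,,,,ug_per_L,33.7,58.3,aligned,,
LU3,LU,central_west,2018,2018,spot_urine,nonsmoker,GAMA,12,11.69,,,,,,,,,ug_per_L,33.7,58.3,aligned,,
FR1,FR,central_west,2014,2014,spot_urine,nonsmoker,AAMA,36,68.25,,,,,,,,,ug_per_L,31.4,50,aligned,,
FR1,FR,central_west,2014,2014,spot_urine,nonsmoker,GAMA,36,8.2,,,,,,,,,ug_per_L,31.4,50,aligned,,
FR1,FR,central_west,2014,2014,spot_urine,smoker,AAMA,27,278.72,,,,,,,,,ug_per_L,31.4,50,aligned,,
FR1,FR,central_west,2014,2014,spot_urine,smoker,GAMA,27,26.15,,,,,,,,,ug_per_L,31.4,50,aligned,,
FR2,FR,central_west,2015,2015,spot_urine,nonsmoker,AAMA,138,85.94,,,,,,,,,ug_per_L,32.5,39.9,aligned,,
FR2,FR,central_west,2015,2015,spot_urine,nonsmoker,GAMA,138,10.35,,,,,,,,,ug_per_L,32.5,39.9,aligned,,
FR2,FR,central_west,2015,2015,spot_urine,smoker,AAMA,64,304.32,,,,,,,,,ug_per_L,32.5,39.9,aligned,,
FR2,FR,central_west,2015,2015,spot_urine,smoker,GAMA,64,29.29,,,,,,,,,ug_per_L,32.5,39.9,aligned,,
FR3,FR,central_west,2016,2016,spot_urine,nonsmoker,AAMA,23,89.22,,,,,,,,,ug_per_L,34.0,34.8,aligned,,
FR3,FR,central_west,2016,2016,spot_urine,nonsmoker,GAMA,23,11.43,,,,,,,,,ug_per_L,34.0,34.8,aligned,,
FR3,FR,central_west,2016,2016,spot_urine,smoker,AAMA,10,222.21,,,,,,,,,ug_per_L,34.0,34.8,aligned,,
FR3,FR,central_west,2016,2016,spot_urine,smoker,GAMA,10,21.42,,,,,,,,,ug_per_L,34.0,34.8,aligned,,
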