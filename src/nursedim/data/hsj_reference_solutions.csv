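date,care_hours,nurse_ratio_pct,nurse_morning,nurse_afternoon,nurse_night1,nurse_night2,tech_morning,tech_afternoon,tech_night1,tech_night2
2016-09-07,164.0,35,3,4,2,2,7,8,1,1
2016-09-08,120.6,34,3,3,1,1,5,6,1,1
2016-09-09,124.4,34,3,3,1,1,5,6,1,1
2016-09-10,98.0,34,2,2,2,2,3,4,1,1
2016-09-11,109.4,35,2,3,2,2,4,5,1,1
2016-09-12,113.2,34,2,3,1,1,5,5,1,1
2016-09-13,154.8,34,4,4,1,1,7,7,1,1
2016-09-14,164.0,34,3,4,2,2,7,8,1,1
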