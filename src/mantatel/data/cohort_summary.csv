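animal_id,wingspan_cm,sex,maturity,deployment_date,total_detections,track_days,detection_days,ri,min_distance_km,max_absence_days,satellite_tag
M3,308,M,mature,2012-10-28,2782,702,352,0.50,1554.0,35,none
M6,326,F,mature,2012-10-29,2701,709,283,0.40,1032.3,46,none
M7,304,M,mature,2012-10-29,881,699,134,0.19,493.5,80,none
M8,325,F,mature,2012-10-29,2491,710,259,0.36,1126.5,56,none
M9,326,M,mature,2012-10-29,2621,715,316,0.44,1362.0,25,none
M10,246,F,immature,2012-10-30,8659,722,383,0.53,2771.8,96,none
M11,272,M,immature,2012-10-30,124,122,21,0.17,73.7,48,none
M12,282,M,immature,2012-10-30,2172,700,220,0.31,991.0,60,none
M13,366,F,mature,2012-10-30,1955,527,188,0.36,736.5,37,SPOT
M15,264,M,immature,2012-10-30,4063,703,393,0.56,1811.0,29,none
M16,346,F,mature,2012-10-30,3270,711,300,0.42,1174.4,32,none
M17,344,F,mature,2012-10-31,2463,714,255,0.36,1006.9,71,none
M18,316,M,mature,2012-10-31,2786,712,308,0.43,1128.8,24,none
M20,296,M,mature,2012-10-31,1032,707,125,0.18,483.1,149,PSAT
M21,320,F,mature,2012-10-31,1739,691,196,0.28,673.3,71,PSAT
M22,344,F,mature,2012-10-31,3280,718,276,0.38,1321.8,32,none
M23,362,F,mature,2012-11-01,4201,715,368,0.51,1596.9,22,none
M24,314,M,mature,2012-11-01,3298,431,268,0.62,1298.7,58,none
M25,316,M,mature,2012-11-01,913,265,79,0.30,412.8,53,none
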