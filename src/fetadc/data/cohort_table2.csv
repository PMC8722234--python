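patient,timepoint,fet_vol_pat_raw,fet_vol_pat_mm3,tbr_mean,tbr_max,adc_vol_pat_raw,adc_vol_pat_mm3,mean_adc_vol_pat,rano
1,baseline,4617,4617,1.97,3.12,15,15,586.3,PD
1,post,"1,0370",10370,1.99,3.28,384,384,604.7,PD
2,baseline,"1,7322",17322,2.07,3.50,913,913,563.0,SD
2,post,"1,3009",13009,2.18,4.14,69,69,579.0,SD
3,baseline,3699,3699,1.69,2.18,627,627,666.7,PD
3,post,8578,8578,1.78,2.55,1280,1280,689.7,PD
4,baseline,9785,9785,1.88,3.09,1252,1252,645.5,PD
4,post,"1,6413",16413,2.07,3.43,178,178,733.9,PD
5,baseline,1242,1242,1.83,2.33,17,17,668.1,SD
5,post,7137,7137,2.11,3.67,290,290,687.1,SD
6,baseline,"1,0710",10710,1.79,3.42,631,631,657.9,PD
6,post,2548,2548,1.69,2.11,41,41,637.8,PD
7,baseline,1873,1873,1.79,2.35,253,253,667.7,SD
7,post,1486,1486,1.82,2.39,335,335,646.3,SD
8,baseline,9052,9052,1.79,2.47,240,240,383.2,SD
8,post,"1,1109",11109,1.79,2.77,328,328,566.1,SD
9,baseline,6173,6173,1.99,3.50,184,184,626.1,SD
9,post,4007,4007,1.87,2.77,359,359,558.4,SD
10,baseline,3941,3941,1.87,3.25,266,266,606.7,PD
10,post,8475,8475,1.94,3.20,833,833,644.3,PD
11,baseline,"2,2115",22115,1.98,3.44,/,,,PD
11,post,"6,0399",60399,2.19,3.40,2579,2579,640.1,PD
12,baseline,"3,9114",39114,2.04,4.13,666,666,402.1,PD
12,post,"11,1268",111268,2.14,4.37,1571,1571,461.5,PD
13,baseline,3955,3955,1.87,2.88,398,398,677.3,SD
13,post,4964,4964,1.89,2.78,823,823,675.4,SD
14,baseline,"5,7593",57593,2.20,4.29,/,,,PD
14,post,"3,9486",39486,2.00,3.11,/,,,PD
15,baseline,"1,0754",10754,1.94,3.64,234,234,606.2,PD
15,post,"9,9238",99238,2.35,4.64,2916,2916,643.5,PD
16,baseline,"2,4646",24646,2.12,3.97,/,,,SD
16,post,"1,4428",14428,1.98,3.17,717,717,586.4,SD
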