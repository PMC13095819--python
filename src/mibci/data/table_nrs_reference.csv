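patient,period,measure,q25,median,q75,variation_pct
01-01,m-1,nrs_min,2,2,2,
01-01,m-1,nrs_avg,5,6,7,
01-01,m-1,nrs_max,8,8,9,
01-01,w1,nrs_min,2,2,2,0
01-01,w1,nrs_avg,4,5,5,-16.66
01-01,w1,nrs_max,8,8,9,0
01-01,w2,nrs_min,2,2,2,0
01-01,w2,nrs_avg,4,4,5,-33.33
01-01,w2,nrs_max,7,8,8,0
01-01,w3,nrs_min,2,2,2,0
01-01,w3,nrs_avg,4.5,5,5,-16.66
01-01,w3,nrs_max,7,8,8,0
01-01,w4,nrs_min,2,2,2,0
01-01,w4,nrs_avg,5,6,6,0
01-01,w4,nrs_max,7,8,8.5,0
01-01,w12-w23,nrs_min,2,2,2,0
01-01,w12-w23,nrs_avg,4.75,5,6.25,-16.66
01-01,w12-w23,nrs_max,8,9,9.25,12.5
01-02,m-1,nrs_min,2,3,4,
01-02,m-1,nrs_avg,6,7,7,
01-02,m-1,nrs_max,8,8.5,9,
01-02,w1,nrs_min,3,3,4,0
01-02,w1,nrs_avg,4.5,5,6,-28.57
01-02,w1,nrs_max,6.5,7,8,-17.64
01-02,w2,nrs_min,2.5,3,4.5,0
01-02,w2,nrs_avg,3.5,5,6,-28.57
01-02,w2,nrs_max,6,7,7.5,-17.64
01-02,w3,nrs_min,3.5,4,4,33.33
01-02,w3,nrs_avg,4.5,5,6,-28.57
01-02,w3,nrs_max,7,7,8,-17.64
01-02,w4,nrs_min,3.5,4,5,33.33
01-02,w4,nrs_avg,5.5,6,6,-14.28
01-02,w4,nrs_max,7,7,7.5,-17.64
01-02,w12-w23,nrs_min,1,1,1,-66.66
01-02,w12-w23,nrs_avg,4,5,5,-28.57
01-02,w12-w23,nrs_max,6,7,7,-17.64
01-04,m-1,nrs_min,0,0,0,
01-04,m-1,nrs_avg,2,2,3,
01-04,m-1,nrs_max,4,8,8,
01-04,w1,nrs_min,0,0,0,
01-04,w1,nrs_avg,2,2,2,0
01-04,w1,nrs_max,6,6,8,-25
01-04,w2,nrs_min,0,0,0,
01-04,w2,nrs_avg,2,2,2,0
01-04,w2,nrs_max,6,6,7,-25
01-04,w3,nrs_min,0,0,0,
01-04,w3,nrs_avg,2,2,2,0
01-04,w3,nrs_max,6,6,7,-25
01-04,w4,nrs_min,0,0,0,
01-04,w4,nrs_avg,2,2,2,0
01-04,w4,nrs_max,6,8,8,0
01-04,w12-w23,nrs_min,0,0,0,
01-04,w12-w23,nrs_avg,4,4.5,5,125
01-04,w12-w23,nrs_max,8,8,9,0
01-05,m-1,nrs_min,4,4,5,
01-05,m-1,nrs_avg,6,7,7,
01-05,m-1,nrs_max,9,9,9,
01-05,w1,nrs_min,4,4,4,0
01-05,w1,nrs_avg,6,6,6,-14.28
01-05,w1,nrs_max,9,9,9,0
01-05,w2,nrs_min,3,3,4,-25
01-05,w2,nrs_avg,6,6,6,-14.28
01-05,w2,nrs_max,8.5,9,9,0
01-05,w3,nrs_min,3,3,3,-25
01-05,w3,nrs_avg,6,6,6,-14.28
01-05,w3,nrs_max,8,8,8,-11.11
01-05,w4,nrs_min,3,3,3,-25
01-05,w4,nrs_avg,6,6,6,-14.28
01-05,w4,nrs_max,7.5,8,8,-11.11
01-05,w12-w23,nrs_min,2,3,3,-25
01-05,w12-w23,nrs_avg,5,5,6,-28.57
01-05,w12-w23,nrs_max,7.5,8,8,-11.11
01-06,m-1,nrs_min,0,0,0,
01-06,m-1,nrs_avg,2,3,3,
01-06,m-1,nrs_max,6,7,7.25,
01-06,w1,nrs_min,0,1,1,
01-06,w1,nrs_avg,1.5,2,2.5,-33.33
01-06,w1,nrs_max,5,6,6.5,-14.28
01-06,w2,nrs_min,0,0,0.75,
01-06,w2,nrs_avg,2.25,3,3,0
01-06,w2,nrs_max,6,6.5,7,-7.14
01-06,w3,nrs_min,0,0,0,
01-06,w3,nrs_avg,1,2,2,-33.33
01-06,w3,nrs_max,3.5,4,6.5,-42.85
01-06,w4,nrs_min,0,0,0,
01-06,w4,nrs_avg,2,2,2.5,-33.33
01-06,w4,nrs_max,5,5,5.5,-28.57
01-06,w12-w23,nrs_min,0,0,1,
01-06,w12-w23,nrs_avg,3,3,3,0
01-06,w12-w23,nrs_max,6.75,7,7,0
All,m-1,nrs_min,0,2,4,
All,m-1,nrs_avg,3,5,7,
All,m-1,nrs_max,7,8,9,
All,w1,nrs_min,0,2,3.5,0
All,w1,nrs_avg,2,4,6,-20
All,w1,nrs_max,6,8,9,0
All,w2,nrs_min,0,2,3,0
All,w2,nrs_avg,3,4,6,-20
All,w2,nrs_max,6,7,8,-12.5
All,w3,nrs_min,0,2,3,0
All,w3,nrs_avg,2,5,6,0
All,w3,nrs_max,6,7,8,-12.5
All,w4,nrs_min,0,2,3,0
All,w4,nrs_avg,2,5,6,0
All,w4,nrs_max,6,7,8,-12.5
All,w12-w23,nrs_min,0,1,2,-50
All,w12-w23,nrs_avg,4,5,5,0
All,w12-w23,nrs_max,7,8,8.75,0
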