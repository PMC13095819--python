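patient,period,q25,median,q75,variation_pct,ambiguous
01-01,m-1,2.220,2.945,3.900,,True
01-01,w1,2.275,2.370,2.565,-19.52,True
01-01,w2,1537.5,1770,2242.5,-39.9,True
01-01,w3,1357.5,1.540,1.695,-47.71,True
01-01,w4,1745,2065,2.345,-29.88,True
01-02,m-1,94.562,569.235,1089.747,,False
01-02,w1,30.26,42,82.83,-92.62,False
01-02,w2,27.745,56.51,71.905,-90.07,False
01-02,w3,42.5,47,133.25,-91.74,False
01-02,w4,30.25,46.5,88.5,-91.83,False
01-04,m-1,153.033,550.133,883.033,,False
01-04,w1,225.166,232.266,250.216,-57.78,False
01-04,w2,230.091,330.266,414.166,-39.97,False
01-04,w3,138.15,180.2,293.033,-67.24,False
01-04,w4,258.166,296.2,376.583,-46.16,False
01-05,m-1,11.615,14.025,16.71,,False
01-05,w1,6.155,7.27,7.755,-48.16,False
01-05,w2,4.59,7.36,9.055,-47.52,False
01-05,w3,3.28,3.36,3.455,-76.04,False
01-05,w4,2.845,3.12,3.585,-77.75,False
01-06,m-1,25.5,59,285,,False
01-06,w1,128.5,218,530.5,269.49,False
01-06,w2,173,367,483,522.03,False
01-06,w3,11,19,145.5,-67.8,False
01-06,w4,7,9,11.5,-84.75,False
All,m-1,22.255,335,1274.015,,False
All,w1,19.56,218,530.5,-34.93,False
All,w2,20.49,150.3,518,-55.13,False
All,w3,11,120.2,560.633,-64.12,False
All,w4,7,46.5,376.583,-86.12,False
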