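site,seed_density,spathe_density,n_samples,n_mlg,R,Na,He,Ho,degree,betweenness,inflow
Ricketts Point,56.61,14.76,45,19,0.41,5.22,0.60,0.60,3,2.16,1.01
Williamstown,350.32,105.13,45,21,0.45,5.11,0.61,0.56,3,2.67,1.18
Jawbone,28.31,7.38,42,31,0.73,5.56,0.66,0.57,1,0,1.48
Altona,24.06,10.45,45,28,0.61,6.22,0.62,0.62,3,4.17,0.97
Kirk Point,629.22,629.42,45,24,0.52,5.56,0.68,0.59,8,41.50,9.47
Avalon,4856.18,2611.73,45,41,0.91,6.33,0.63,0.56,6,5.83,9.92
Point Henry,9140.83,1316.32,45,40,0.89,5.89,0.63,0.49,4,0,1.58
Grand Scenic,3269.63,2311.09,45,38,0.84,5.67,0.61,0.64,5,0.67,11.79
Point Richards,987.97,1176.76,43,40,0.93,6.22,0.63,0.56,7,20.50,17.68
Edwards Point,14.15,247.16,45,25,0.55,4.89,0.60,0.63,1,0,4.54
North Swan Bay,3227.16,2705.80,45,39,0.86,6.33,0.60,0.56,1,0,4.55
South Swan Bay,1241.32,1167.53,43,25,0.57,5.67,0.63,0.49,2,13.00,0.79
Point Lonsdale,,,45,9,0.18,2.78,0.42,0.64,0,0,0.15
Mud Islands,806.79,31.36,44,33,0.74,5.89,0.65,0.56,2,0,4.14
Blairgowrie,6933.09,1706.11,45,39,0.86,5.56,0.64,0.58,1,0,0.44
Rosebud,1214.17,1579.77,45,20,0.43,6.44,0.64,0.55,7,24.50,0.38
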