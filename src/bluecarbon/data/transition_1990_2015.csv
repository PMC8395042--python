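from\to,Offshore waters,Tidal flat,Coastal marsh,Grassland,River and lake,Aquaculture fish pond,Paddy field,Reservoir,Construction land,Rainfed cropland,Transfer-Out Area
Offshore waters,0.00,158.94,124.30,1.68,1.87,61.17,31.21,50.92,14.57,24.56,469.22
Tidal flat,33.88,0.00,76.17,2.71,0.29,37.02,45.73,10.41,15.70,27.59,249.50
Coastal marsh,2.73,2.55,0.00,5.65,0.31,24.40,41.63,1.87,6.32,26.65,112.11
Grassland,0.08,0.02,0.51,0.00,0.00,0.35,0.28,0.06,0.22,0.36,1.88
River and lake,0.01,0.05,0.01,0.00,0.00,0.02,0.00,0.00,0.03,0.01,0.13
Aquaculture fish pond,0.80,1.11,8.39,0.71,0.02,0.00,4.10,0.53,4.06,4.30,24.02
Paddy field,0.12,0.07,0.96,0.21,0.00,1.54,0.00,0.06,0.33,1.33,4.62
Reservoir,0.19,0.02,0.10,0.01,0.02,0.04,0.04,0.00,0.13,0.36,0.91
Construction land,0.02,0.15,0.14,0.03,0.00,0.26,0.01,0.12,0.00,0.37,1.10
Rainfed cropland,0.10,0.72,4.26,0.78,0.01,2.88,1.94,0.54,1.23,0.00,12.46
Transfer-in area,37.93,163.63,214.84,11.78,2.52,127.68,124.94,64.51,42.59,85.53,
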