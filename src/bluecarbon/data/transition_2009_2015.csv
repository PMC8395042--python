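from\to,Offshore waters,Tidal flat,Coastal marsh,Grassland,River and lake,Aquaculture fish pond,Paddy field,Reservoir,Construction land,Rainfed cropland,Transfer-Out Area
Offshore waters,0.00,148.24,20.22,0.07,1.34,9.95,1.20,2.24,3.44,2.91,189.61
Tidal flat,54.25,0.00,53.78,0.34,0.59,21.78,6.18,2.45,3.85,7.46,150.68
Coastal marsh,0.61,8.41,0.00,3.07,0.08,29.84,30.63,5.44,4.60,21.16,103.84
Grassland,0.00,0.02,1.06,0.00,0.00,0.83,2.07,0.01,0.21,1.42,5.62
River and lake,0.05,0.00,0.81,0.01,0.00,0.58,0.50,0.21,0.09,0.19,2.44
Aquaculture fish pond,1.66,4.29,28.36,0.67,0.31,0.00,12.05,6.92,5.49,9.94,69.69
Paddy field,0.01,0.24,12.26,4.95,0.18,9.92,0.00,0.17,0.81,16.71,45.25
Reservoir,6.28,2.83,7.43,0.11,0.83,6.37,4.53,0.00,0.38,1.38,30.14
Construction land,0.53,1.98,1.90,0.14,0.02,5.09,1.00,0.39,0.00,4.61,15.66
Rainfed cropland,0.03,0.80,19.36,2.72,0.01,15.14,28.19,0.40,5.46,0.00,72.11
Transfer-in area,63.42,166.81,145.18,12.08,3.36,99.50,86.35,18.23,24.33,65.78,
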