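from\to,Offshore waters,Tidal flat,Coastal marsh,Grassland,River and lake,Aquaculture fish pond,Paddy field,Reservoir,Construction land,Rainfed cropland,Transfer-Out Area
Offshore waters,0.00,128.47,14.58,0.03,0.76,13.33,0.94,49.82,5.54,5.47,218.94
Tidal flat,66.72,0.00,81.66,0.50,1.24,35.50,12.72,22.83,8.56,23.39,253.12
Coastal marsh,4.41,6.75,0.00,2.01,0.12,18.96,14.52,1.01,6.72,21.35,75.85
Grassland,0.00,0.00,0.29,0.00,0.00,0.13,0.85,0.00,0.08,0.37,1.72
River and lake,0.00,0.18,0.40,0.02,0.00,0.29,0.11,0.00,0.31,0.29,1.60
Aquaculture fish pond,8.57,6.23,13.48,1.29,0.18,0.00,9.53,2.00,6.22,12.01,59.51
Paddy field,0.78,1.16,16.06,0.79,0.08,7.52,0.00,1.19,2.45,8.56,38.59
Reservoir,1.13,0.26,0.23,0.00,0.00,0.42,0.01,0.00,1.02,0.18,3.25
Construction land,0.14,1.11,0.92,0.06,0.00,2.86,0.32,0.17,0.00,5.30,10.88
Rainfed cropland,0.35,2.62,9.08,1.19,0.07,6.12,35.86,0.19,2.36,0.00,57.84
Transfer-in area,82.10,146.78,136.70,5.97,2.45,85.13,74.86,77.21,33.26,76.92,
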