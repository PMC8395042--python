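from\to,Offshore waters,Tidal flat,Coastal marsh,Grassland,River and lake,Aquaculture fish pond,Paddy field,Reservoir,Construction land,Rainfed cropland,Transfer-Out Area
Offshore waters,0.00,238.49,36.31,0.12,0.01,22.39,7.69,4.61,5.45,5.98,321.05
Tidal flat,33.45,0.00,88.42,0.50,0.45,19.12,15.77,1.14,3.15,18.67,180.67
Coastal marsh,3.11,6.82,0.00,0.82,0.91,24.97,17.95,0.12,3.27,45.79,103.76
Grassland,0.07,0.12,0.33,0.00,0.01,0.54,0.49,0.02,0.13,0.27,1.98
River and lake,0.02,0.04,0.01,0.00,0.00,0.04,0.00,0.00,0.01,0.01,0.13
Aquaculture fish pond,1.12,4.60,6.38,0.10,0.18,0.00,3.70,0.03,1.11,3.55,20.77
Paddy field,0.12,0.33,0.91,0.07,0.02,1.37,0.00,0.04,0.40,1.57,4.83
Reservoir,0.48,0.22,0.01,0.00,0.00,0.09,0.01,0.00,0.18,0.08,1.07
Construction land,0.04,0.16,0.03,0.02,0.00,0.27,0.15,0.07,0.00,0.33,1.07
Rainfed cropland,0.25,1.50,3.81,0.17,0.02,3.55,2.49,0.17,0.72,0.00,12.68
Transfer-in area,38.66,252.28,136.21,1.80,1.60,72.34,48.25,6.20,14.42,76.25,
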