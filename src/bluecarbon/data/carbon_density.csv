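code,name,c_above,c_below,c_soil,c_dead,c_total
1,Offshore waters,2.0,1.0,11.0,0.0,14.0
2,Tidal flat,2.8,1.8,13.8,0.0,18.4
3,Coastal marsh,26.5,10.5,26.6,0.4,32.4
4,Grassland,2.5,11.1,26.5,0.2,40.3
5,River and lake,1.5,0.5,11.0,0.0,13.0
6,Aquaculture fish pond,0.5,0.0,12.0,0.0,12.5
7,Paddy field,9.0,4.0,38.6,0.3,25.5
8,Reservoir,1.0,0.5,11.0,0.0,12.5
9,Construction land,0.0,0.0,8.0,0.0,8.0
10,Rainfed cropland,5.0,4.0,31.7,0.3,20.5
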