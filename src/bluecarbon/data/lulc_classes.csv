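code,name,group
1,Offshore waters,waters
2,Tidal flat,natural wetland
3,Coastal marsh,natural wetland
4,Grassland,other land
5,River and lake,natural wetland
6,Aquaculture fish pond,artificial wetland
7,Paddy field,artificial wetland
8,Reservoir,artificial wetland
9,Construction land,other land
10,Rainfed cropland,other land
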