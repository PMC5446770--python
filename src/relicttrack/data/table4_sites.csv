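site,lat,lon,season,stopover_frequency,accumulated_days
Chahai Nur,41.462,113.901,autumn,6,105
Xiyan Nur,41.522,114.221,autumn,4,26
Anguli Nur,41.289,114.431,autumn,4,20
Cetian Reservoir,39.980,113.677,autumn,1,14
Xiahewan Reservoir,39.750,114.300,autumn,1,13
Kangbu Nur,41.273,113.890,autumn,2,12
Huanggai Nur & Sangai Nur,41.350,114.726,autumn,3,11
Wulanhushaohaizi & Baiyin Nur,41.524,113.270,autumn,1,10
Hanhaizi,41.462,113.523,autumn,1,7
Huangqihai,40.830,113.280,autumn,2,6
Daihai,40.583,112.757,autumn,1,2
Yanghe Reservoir,40.543,115.106,autumn,1,1
Dongyulin Reservoir,39.361,112.623,autumn,1,1
Wulanhushaohaizi & Baiyin Nur,41.524,113.270,spring,1,6
Shuangrushan Reservoir,38.538,112.607,spring,1,1
Dangyangqiao Reservoir,40.036,111.625,spring,1,1
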