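province,latitude,all_f,all_r2,all_p,all_start,all_end,herb_f,herb_r2,herb_p,herb_start,herb_end,woody_f,woody_r2,woody_p,woody_start,woody_end
Hainan,19.222,40.7,0.783,<0.001,1,12,19.4,0.625,<0.001,1,12,15.8,0.574,0.003,1,12
Guangxi,23.015,15.8,0.573,0.003,1,12,16.6,0.587,0.002,1,12,6.6,0.337,0.028,1,12
Guangdong,23.277,24.8,0.684,0.001,1,12,20.1,0.63,0.001,1,12,7.6,0.376,0.02,1,12
Yunnan,24.141,15.6,0.593,0.003,2,12,14.8,0.605,0.005,3,12,5.5,0.29,0.040,1,12
Fujian,26.004,31.1,0.732,<0.001,1,12,18.5,0.614,0.002,1,12,9.2,0.426,0.013,1,12
Guizhou,26.668,18.9,0.642,0.002,2,12,42.3,0.821,<0.001,3,12,4.4,0.238,0.061,1,12
Jiangxi,27.735,12.9,0.569,0.007,3,12,60.7,0.869,<0.001,3,12,3.3,0.186,0.103,2,12
Hunan,28.016,17.6,0.624,0.002,2,12,48.7,0.841,<0.001,3,12,3.7,0.209,0.088,2,12
Zhejiang,29.105,30.1,0.784,0.001,3,11,132.4,0.943,<0.001,3,11,2.0,0.113,0.198,3,11
Sichuan,30.277,19.6,0.699,0.003,3,11,19.9,0.73,0.004,4,11,2.9,0.196,0.129,3,11
Xizang,31.101,9.6,0.519,0.017,3,11,12.2,0.616,0.013,4,11,4.5,0.306,0.071,3,11
Anhui,32.014,25.3,0.751,0.002,3,11,113.9,0.934,<0.001,3,11,2.9,0.212,0.14,3,10
Hubei,32.014,12.9,0.599,0.009,3,11,31.8,0.794,0.0008,3,11,2.6,0.185,0.159,3,10
Jiangsu,32.472,53.4,0.868,<0.001,3,11,139.3,0.945,<0.001,3,11,2.0,0.109,0.202,3,11
Henan,33.800,31.8,0.794,<0.001,3,11,44.2,0.844,<0.001,3,11,3.3,0.244,0.121,3,10
Shanxi,34.115,95.0,0.94,<0.001,4,10,69.6,0.919,<0.001,4,10,4.9,0.357,0.069,3,10
Qinghai,35.723,16.3,0.719,0.009,4,10,51.2,0.909,0.002,5,10,17.4,0.767,0.014,4,9
Gansu,35.949,37.2,0.858,0.002,4,10,38.3,0.861,0.002,4,10,4.6,0.336,0.077,3,10
Shandong,36.178,69.7,0.896,<0.001,3,11,55.1,0.871,<0.001,3,11,3.3,0.248,0.119,3,10
Ningxia,37.366,35.9,0.853,0.002,4,10,37.3,0.858,0.002,4,10,2.7,0.216,0.164,4,10
Shaanxi,37.699,29.6,0.803,0.002,3,10,34.7,0.849,0.002,4,10,3.1,0.227,0.131,3,10
Hebei,38.222,74.3,0.924,<0.001,4,10,43.6,0.877,0.001,4,10,6.5,0.436,0.044,3,10
Inner Mongolia,41.386,20.9,0.768,0.006,4,10,25.1,0.828,0.007,5,10,4.0,0.332,0.103,4,10
Liaoning,41.474,42.3,0.874,0.001,4,10,31.6,0.836,0.002,4,10,1.2,0.035,0.338,4,9
Xinjiang,42.002,28.2,0.819,0.003,4,10,27.7,0.816,0.003,4,10,8.3,0.548,0.035,4,10
Jilin,43.501,27.8,0.817,0.003,4,10,22.4,0.781,0.005,4,10,4.6,0.373,0.086,3,9
Heilongjiang,46.770,85.2,0.934,<0.001,4,10,54.9,0.9,<0.001,4,10,1.0,0.166,0.365,4,10
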