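compound,product,lb,ub
Acrylonitrile,htp,0.142,0.320
Acrylonitrile,cigarette,30.82,32.71
Acetaldehyde,htp,143,321
Acetaldehyde,cigarette,1048,2358
Benzo[a]pyrene,htp,0.00092,0.00207
Benzo[a]pyrene,cigarette,0.0093,0.0209
"1,3-Butadiene",htp,0.212,0.477
"1,3-Butadiene",cigarette,51.02,114.79
Ethylene oxide,htp,0.162,0.364
Ethylene oxide,cigarette,21.14,47.56
Formaldehyde,htp,3.560,8.010
Formaldehyde,cigarette,41.53,93.45
Nitrobenzene,htp,0.00006,0.00051
Nitrobenzene,cigarette,0.00015,0.0327
Propylene oxide,htp,0.102,0.229
Propylene oxide,cigarette,1.005,2.260
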