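group,E,Fd,Fp,Eh,V
CH3,,390,0,0,33.5
CH2,,250,0,0,16.1
CH_CH3,,460,0,0,32.5
C_CH3,,320,0,0,14.3
phenyl,,1210,95,0,71.4
phenylene_p,,1070,95,0,52.4
COOH,,480,380,8600,28.5
COO,,350,430,6100,18.0
CO,,260,690,1800,10.8
OH,,190,450,17500,10.0
O,,90,360,2600,3.8
N_CH2,,260,720,4400,7.1
ring,,170,0,0,16.0
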