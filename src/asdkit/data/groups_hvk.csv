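group,E,Fd,Fp,Eh,V
CH3,,420,0,0,33.5
CH2,,270,0,0,16.1
CH_CH3,,500,0,0,32.5
C_CH3,,350,0,0,14.3
phenyl,,1430,110,0,71.4
phenylene_p,,1270,110,0,52.4
COOH,,530,420,10000,28.5
COO,,390,490,7000,18.0
CO,,290,770,2000,10.8
OH,,210,500,20000,10.0
O,,100,400,3000,3.8
N_CH2,,290,800,5000,7.1
ring,,190,0,0,16.0
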