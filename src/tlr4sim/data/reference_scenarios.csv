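species,base_conc,sensitivity,c_min_resp,r_min_resp,c_max_resp,r_max_resp,c_avg_resp,r_avg_resp
CD14,10000,2.31E-04,3100,0.31,60700,6.07,11000,1.10
MD2,10000,1.87E-04,10100,1.01,11000,1.10,10600,1.06
TLR4,10000,1.76E-03,2600,0.26,32900,3.29,12000,1.20
TRAM,10000,1.19E-02,5200,0.52,10500,1.05,7800,0.78
MAL,10000,-1.16E-02,15100,1.51,7400,0.74,10800,1.08
TRIF,285,-3.40E-04,285,1.00,285,1.00,285,1.00
MyD88,285,9.09E-05,290.7,1.02,316.35,1.11,302.1,1.06
RP1,285,-3.41E-04,467.4,1.64,153.9,0.54,233.7,0.82
IRAK1,1100,3.08E-05,88,0.08,1793,1.63,704,0.64
IRAK4,285,6.23E-06,285,1.00,285,1.00,285,1.00
TRAF6,1100,4.74E-03,913,0.83,2882,2.62,1881,1.71
TAK1,10000,1.25E-01,6700,0.67,13400,1.34,9600,0.96
Ikk_Complex,10000,3.01E-01,6500,0.65,17300,1.73,9800,0.98
IkB-alpha,31.6,-1.45E-03,56.564,1.79,24.016,0.76,31.916,1.01
NFkB,31.6,3.24E-03,4.108,0.13,173.8,5.50,46.768,1.48
IRAK4_MyD88,812,1.01E-04,828.24,1.02,901.32,1.11,860.72,1.06
RP1_TRIF,812,-2.22E-03,1331.68,1.64,438.48,0.54,665.84,0.82
IkB_NFkB,9970,4.60E-01,997,0.10,98204.5,9.85,14855.3,1.49
IRAK1_IRAK4_MyD88,8900,5.13E-04,712,0.08,14507,1.63,5696,0.64
RP1_TRIF_TRAF6,8900,1.50E-02,4005,0.45,38270,4.30,12460,1.40
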