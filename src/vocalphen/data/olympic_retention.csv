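species_code,cs_threshold,n_total,n_retained,fraction_published,attempted_Low,fit_Low,detected_Low,attempted_Mid,fit_Mid,detected_Mid
AMRO,0.146,16677,10743,0.64,1,1,1,1,1,1
BRCR,0.85,509399,20201,0.04,1,1,1,1,1,1
BTYW,1,220160,0,0.00,0,0,0,0,0,0
CAJA,0.216,10840,5800,0.54,1,1,1,1,1,1
CBCH,0.335,710315,359933,0.51,1,1,1,1,1,1
DEJU,0.116,241368,217738,0.90,1,1,1,1,1,1
EVGR,0.18,20948,17792,0.85,1,1,1,1,1,1
GCKI,0.846,1401440,68651,0.05,1,1,1,1,1,1
HAFL,0.571,107416,44027,0.41,1,1,1,1,1,1
HETH,0.277,57210,32260,0.56,0,0,0,1,1,1
NOFL,0.226,24629,17504,0.71,1,1,0,1,1,1
OSFL,0.243,44227,34151,0.77,1,1,1,1,1,1
PAWR,0.42,1524842,1027812,0.67,1,1,1,1,1,1
PISI,0.089,61851,61851,1.00,1,1,1,1,1,1
PIWO,0.624,19764,7223,0.37,1,1,1,0,0,0
RBNU,0.022,660600,660600,1.00,1,1,0,1,1,1
RECR,0.107,533624,517032,0.97,1,1,1,1,1,1
RUHU,0.995,2945,6,0.00,1,0,0,1,0,0
SOGR,0.462,63505,15691,0.25,1,1,1,1,1,1
STJA,0.221,92441,69439,0.75,1,1,1,1,1,0
SWTH,0.256,8681,4848,0.56,1,0,0,0,0,0
TOWA,0.872,818191,46607,0.06,1,1,1,1,1,1
VATH,0.462,944650,439384,0.47,1,1,1,1,1,1
WAVI,0.492,10363,2942,0.28,1,1,1,1,0,0
WEFL,0.154,1528095,1323174,0.87,1,1,1,1,1,1
WETA,0.188,40498,26318,0.65,1,1,1,1,1,1
WEWP,0.53,2409,809,0.34,1,0,0,0,0,0
WIWA,0.675,55494,8046,0.14,1,1,1,0,0,0
YRWA,0.548,16090,2150,0.13,1,0,0,1,1,1
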