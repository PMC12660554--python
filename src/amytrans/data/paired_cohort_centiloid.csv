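id,diagnosis,cl_fbb,cl_pib_only,cl_pib_mr,cl_pib
elder_1008,AD,39.14,65.78,58.97,64.14
elder_1009,AD,92.67,99.9,87.89,93.81
elder_1015,AD,15.78,26.9,24.12,30.53
elder_1023,AD,63.75,60.86,63.75,65.01
elder_1028,AD,118.43,108.22,105.02,118.27
elder_1031,AD,87.72,70.03,70.62,71.14
elder_1032,AD,75.97,69.67,67.97,72.25
elder_1034,AD,44.18,62.22,66.29,62.45
elder_1019,FTD,10.58,2.88,5.18,1.2
elder_2029,FTD,10.8,7.13,8.03,7.59
elder_1010,HC,12.24,18.57,15.77,16.88
elder_2002,HC,4.37,5.62,19.26,5.98
elder_2005,HC,44.35,39.96,46.75,39.15
elder_2017,HC,1.39,8.29,8.3,7.58
elder_2030,HC,8.46,9.26,13.46,9.78
elder_2032,HC,36.08,40.53,48.12,40.71
Y1001,HC,9.14,8.57,10.5,7.43
Y1002,HC,7.85,5.01,-4.51,4.68
Y1003,HC,-6.48,-0.04,0.67,0.56
Y1004,HC,7.25,5.92,-0.95,8.06
Y1005,HC,13.47,8.54,7.1,7.84
Y1007,HC,15.88,3.57,1.1,4.43
Y1011,HC,13.66,9.19,2.78,11.23
Y1012,HC,14.02,9.54,3.75,8.68
Y1017,HC,11.17,14.33,16.61,13.27
Y1021,HC,13.07,12.54,17.97,11.49
elder_1018,MCI,6.33,1.79,2.86,1.84
elder_1022,MCI,123.37,97.35,90.37,91.43
elder_1024,MCI,2.6,6.78,2.31,5.05
elder_1026,MCI,40.9,36.54,34.04,39.06
elder_1029,MCI,75.03,80.13,88.59,81.42
elder_1030,MCI,62.98,65.25,64.1,66.56
elder_1036,MCI,88.43,93.65,82.62,90.46
elder_1037,MCI,119.29,121.33,133.44,117.31
elder_1038,MCI,60.2,68.24,81.18,66.77
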