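cruise,station,depth_m,is_dcm,temp_c,salinity,no3no2_umol_l,po4_umol_l,p_star_printed,chl_ug_l,chl_sd,nfr_nmol_l_d,nfr_sd,nfr_status,nfr_lod
SP1714,1,2,False,18.22,33.40,0.05,0.09,0.08,0.173,0.003,2.3,1.3,quantified,0.4
SP1714,1,30,True,11.91,33.41,9.82,0.88,0.27,0.900,0.048,3.1,0.7,quantified,0.4
SP1714,1.1,2,False,16.82,33.41,0.01,0.01,0.01,0.213,0.004,14.2,4.5,quantified,0.7
SP1714,1.1,27,True,12.33,33.36,,,,3.012,0.046,11.5,13.1,quantified,0.5
SP1714,2,2,False,16.32,33.42,0.10,0.07,0.07,0.508,0.003,6.7,0.7,quantified,0.3
SP1714,2,29,True,13.63,33.27,9.05,0.64,0.07,0.950,0.033,3.2,2.0,quantified,0.6
SP1714,3,2,False,,,1.65,0.13,0.03,0.943,0.009,4.8,1.9,quantified,0.6
SP1714,3,25,True,14.37,33.47,,,,0.877,0.013,4.0,0.9,quantified,0.7
SP1714,4,2,False,,,,,,,,5.2,1.4,quantified,0.9
SP1714,4,25,True,14.18,33.32,1.31,0.19,0.11,0.509,0.010,8.2,6.4,quantified,1.0
SP1714,5,2,False,14.54,33.23,0.12,0.10,0.09,0.307,0.013,7.1,3.6,quantified,0.5
SP1714,5,50,True,14.51,33.23,0.28,0.06,0.05,0.283,0.013,6.4,2.9,quantified,0.5
SP1714,7,10,False,14.16,33.31,4.58,0.45,0.16,0.257,0.006,6.1,5.3,quantified,1.1
SP1714,7,32,True,12.15,33.37,12.73,0.75,-0.04,0.275,0.012,9.5,1.6,quantified,0.8
SP1714,9,10,False,17.70,33.43,-0.01,0.05,0.05,0.164,0.016,10.0,2.6,quantified,0.5
SP1714,9,52,True,13.53,33.26,4.38,0.32,0.05,0.398,0.022,9.5,2.6,quantified,0.3
SP1714,10,90,False,14.76,33.31,1.22,0.11,0.04,0.241,0.006,3.2,1.4,quantified,0.2
SP1714,12,2,False,16.10,33.51,0.02,0.06,0.06,0.765,0.127,3.6,2.0,quantified,0.4
SP1714,12,20,True,13.47,33.44,4.97,0.59,0.28,1.884,0.207,3.3,0.9,quantified,0.6
SP1714,13,2,False,14.99,33.59,0.25,0.31,0.29,3.994,0.055,23.0,3.8,quantified,2.3
SP1714,13,10,False,13.60,33.49,2.84,0.33,0.15,4.268,0.173,,,DNQ,2.5
SP1714,13,25,True,13.54,33.58,4.60,0.30,0.02,6.044,0.916,11.1,7.4,quantified,3.0
SP1714,14,2,False,18.03,33.53,0.04,0.14,0.14,0.178,0.009,9.9,4.9,quantified,0.8
SP1714,14,10,False,18.00,33.52,0.02,0.16,0.16,0.174,0.013,9.0,4.1,quantified,0.7
SP1714,14,30,True,14.09,33.18,4.55,0.43,0.15,1.133,0.084,8.0,7.9,quantified,1.4
SP1727,1,2,False,21.76,33.56,0.04,0.02,0.02,0.120,0.007,2.2,0.2,quantified,0.7
SP1727,1,10,False,21.35,33.51,0.00,0.02,0.02,0.149,0.010,5.1,0.2,quantified,1.8
SP1727,1,38,True,14.41,33.32,2.22,0.27,0.13,0.595,0.058,,,BDL,2.8
SP1727,2,2,False,20.46,33.58,0.00,0.03,0.03,0.115,0.005,3.9,0.2,quantified,1.4
SP1727,2,10,False,20.47,33.58,0.00,0.03,0.03,0.110,0.001,5.8,0.8,quantified,2.0
SP1727,2,35,True,13.71,33.25,1.03,0.19,0.13,0.495,0.017,,,BDL,3.3
SP1727,3,3,False,18.91,33.51,0.00,0.02,0.02,0.188,0.013,5.7,0.2,quantified,1.2
SP1727,3,10,False,18.88,33.49,0.00,0.07,0.07,0.201,0.006,6.3,0.4,quantified,1.5
SP1727,3,35,True,14.62,33.16,0.21,0.11,0.10,0.390,0.010,,,BDL,1.0
SP1727,4,3,False,18.58,33.44,0.00,0.07,0.07,0.100,0.001,,,BDL,0.6
SP1727,4,10,False,18.58,33.44,0.00,0.08,0.08,0.095,0.003,,,BDL,0.6
SP1727,4,50,True,14.07,33.20,0.65,0.16,0.12,0.249,0.002,,,BDL,0.5
SP1727,5,3,False,18.90,33.43,0.00,0.09,0.09,0.099,0.001,,,BDL,1.0
SP1727,5,10,False,18.83,33.43,0.00,0.07,0.07,0.105,0.005,,,BDL,0.7
SP1727,5,55,True,14.26,33.34,0.24,0.13,0.12,0.309,0.012,,,BDL,0.5
SP1727,7,3,False,19.95,33.39,0.00,0.07,0.07,0.161,0.007,6.7,0.8,quantified,1.2
SP1727,7,10,False,19.54,33.23,0.00,0.07,0.07,0.196,0.010,16.5,1.8,quantified,3.3
SP1727,7,27,True,13.71,33.23,0.26,0.22,0.20,0.689,0.044,,,BDL,5.4
SP1727,9,3,False,20.77,33.51,0.00,0.03,0.03,0.092,0.012,,,DNQ,0.4
SP1727,9,10,False,20.75,33.50,0.00,0.03,0.03,0.094,0.003,5.8,1.2,quantified,0.9
SP1727,9,55,True,13.85,33.27,1.46,0.23,0.14,0.271,0.014,,,DNQ,0.8
SP1727,11,3,False,21.04,33.56,0.00,,,0.088,0.000,5.9,0.9,quantified,0.6
SP1727,11,10,False,21.02,33.57,0.00,0.04,0.04,0.091,0.003,5.8,0.38,quantified,0.5
SP1727,11,67,True,14.11,33.29,0.06,0.18,0.18,0.431,0.015,,,BDL,0.5
SP1727,12,2,False,20.18,33.44,0.00,0.05,0.05,0.142,0.003,14.1,10.0,quantified,0.3
SP1727,12,10,False,19.76,33.34,0.00,0.05,0.05,0.154,0.010,7.0,0.2,quantified,0.6
SP1727,12,38,True,14.80,33.29,1.73,0.33,0.22,0.678,0.024,,,BDL,0.9
SP1727,13,3,False,21.14,33.50,0.00,0.04,0.04,0.098,0.003,9.3,1.9,quantified,0.5
SP1727,13,10,False,21.14,33.50,0.00,0.05,0.05,0.093,0.001,19.6,1.5,quantified,1.1
SP1727,13,68,True,13.96,33.30,0.78,0.25,0.20,0.269,0.011,1.4,1.3,quantified,1.2
SP1727,14,3,False,21.74,33.57,0.00,0.05,0.05,0.063,0.004,,,nm,
SP1727,14,10,False,21.53,33.56,0.00,0.05,0.05,0.078,0.002,3.4,0.2,quantified,1.1
SP1727,14,50,True,18.28,33.33,0.00,0.08,0.08,0.105,0.005,,,BDL,1.6
SP1727,15,3,False,19.31,33.43,,,,0.021,0.006,7.3,0.6,quantified,0.6
SP1727,15,10,False,19.26,33.41,,,,0.211,0.008,,,DNQ,0.8
SP1727,15,38,True,14.05,33.30,,,,0.868,0.039,,,DNQ,0.6
SP1727,17,3,False,17.67,33.42,0.00,0.05,0.05,0.314,0.129,,,BDL,1.5
SP1727,17,10,False,17.47,33.42,0.00,0.05,0.05,0.388,0.037,,,BDL,1.9
SP1727,17,27,True,15.95,33.28,1.40,0.18,0.09,1.494,0.402,,,BDL,2.9
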