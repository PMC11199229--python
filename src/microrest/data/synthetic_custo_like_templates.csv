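,Fp1,Fp2,F7,F3,Fz,F4,F8,FC5,FC1,FC2,FC6,T7,C3,Cz,C4,T8,TP9,CP5,CP1,CP2,CP6,TP10,P7,P3,Pz,P4,P8,PO9,O1,Oz,O2,PO10
1/A,0.105679,0.089624,0.040482,0.078083,0.154482,0.040341,0.06647,0.297687,-0.238979,0.053957,-0.206215,0.093313,-0.180379,0.323029,-0.044902,-0.203106,-0.222778,-0.009488,0.111603,-0.057934,0.304402,-0.463817,0.102447,-0.108231,0.013284,0.205674,-0.084945,0.102349,-0.084912,-0.095661,0.102339,-0.283898
2/B,0.112519,-0.12483,-0.084185,0.115873,-0.013611,0.153175,-0.425408,0.042947,-0.160562,0.087545,0.34282,0.221538,0.285609,-0.04686,0.005611,-0.008406,-0.151647,-0.329199,0.042356,-0.012013,0.083401,-0.115108,-0.082779,0.045883,0.202365,0.089102,0.192902,0.09523,-0.134597,-0.147861,-0.389432,0.107623
3/C,-0.05793,-0.084117,0.074866,-0.191486,0.38103,0.004106,0.195331,-0.166264,0.332993,0.367542,-0.149595,0.011252,0.126552,0.11046,-0.052587,-0.025754,-0.442181,-0.274785,-0.000149,0.089942,0.010938,0.261028,-0.002798,-0.177356,-0.048242,-0.029649,0.005883,0.017952,-0.194861,-0.121534,-0.00262,0.032029
4/D,0.255653,0.294054,-0.15605,0.067302,0.054154,0.188279,0.083906,-0.026515,0.169488,0.106967,-0.043395,-0.152976,0.052895,-0.136987,-0.00113,-0.029567,0.242918,-0.082221,-0.243463,-0.324796,0.101013,0.106493,-0.013332,-0.384048,0.277293,0.090425,-0.168728,-0.024657,0.256441,-0.157568,-0.205825,-0.196025
5/E,0.041998,-0.063667,0.104725,-0.144505,-0.020562,-0.123659,-0.108431,-0.029024,0.01287,0.083582,-0.023234,0.190434,0.172878,-0.311316,0.060493,0.041029,-0.337395,0.054136,-0.231211,-0.037283,0.035988,-0.302962,0.177328,-0.009131,0.245573,0.059324,-0.300183,-0.226548,0.30804,0.158181,0.2624,0.260131
6/F,-0.151963,0.058752,-0.275496,-0.050615,-0.046669,0.137097,-0.138629,-0.241362,0.076898,0.132078,0.15455,0.002846,-0.05625,0.220582,-0.015755,-0.294024,-0.110207,0.339396,-0.145204,0.314598,0.177462,0.022541,0.169886,-0.014375,0.00975,-0.06474,-0.138385,-0.036253,0.044242,0.386013,-0.327372,-0.139391
7/G,-0.365209,0.170954,0.28602,0.287596,-0.023064,-0.101021,0.002316,-0.006503,-0.350557,0.176316,0.160986,-0.15874,0.065049,0.205742,-0.268737,0.091992,-0.121551,-0.08302,-0.064858,-0.064485,-0.314898,0.172258,0.016974,-0.01759,0.190712,0.046572,-0.262233,0.188846,0.131217,0.077217,-0.004048,-0.064254
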