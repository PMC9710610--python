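gene,Naive,GC,Memory,Plasma
Cd19,6.0,5.0,6.0,1.0
Fas,0.3,6.0,1.0,0.5
Cd38,1.0,6.0,0.5,8.0
Sdc1,0.1,0.1,0.1,10.0
Taci,0.3,0.5,3.0,6.0
Xbp1,1.0,1.5,1.0,9.0
NaiveSig01,4.0,0.4,0.4,0.4
NaiveSig02,4.0,0.4,0.4,0.4
NaiveSig03,4.0,0.4,0.4,0.4
NaiveSig04,4.0,0.4,0.4,0.4
NaiveSig05,4.0,0.4,0.4,0.4
NaiveSig06,4.0,0.4,0.4,0.4
NaiveSig07,4.0,0.4,0.4,0.4
NaiveSig08,4.0,0.4,0.4,0.4
NaiveSig09,4.0,0.4,0.4,0.4
NaiveSig10,4.0,0.4,0.4,0.4
NaiveSig11,4.0,0.4,0.4,0.4
NaiveSig12,4.0,0.4,0.4,0.4
GCSig01,0.4,4.0,0.4,0.4
GCSig02,0.4,4.0,0.4,0.4
GCSig03,0.4,4.0,0.4,0.4
GCSig04,0.4,4.0,0.4,0.4
GCSig05,0.4,4.0,0.4,0.4
GCSig06,0.4,4.0,0.4,0.4
GCSig07,0.4,4.0,0.4,0.4
GCSig08,0.4,4.0,0.4,0.4
GCSig09,0.4,4.0,0.4,0.4
GCSig10,0.4,4.0,0.4,0.4
GCSig11,0.4,4.0,0.4,0.4
GCSig12,0.4,4.0,0.4,0.4
MemorySig01,0.4,0.4,4.0,0.4
MemorySig02,0.4,0.4,4.0,0.4
MemorySig03,0.4,0.4,4.0,0.4
MemorySig04,0.4,0.4,4.0,0.4
MemorySig05,0.4,0.4,4.0,0.4
MemorySig06,0.4,0.4,4.0,0.4
MemorySig07,0.4,0.4,4.0,0.4
MemorySig08,0.4,0.4,4.0,0.4
MemorySig09,0.4,0.4,4.0,0.4
MemorySig10,0.4,0.4,4.0,0.4
MemorySig11,0.4,0.4,4.0,0.4
MemorySig12,0.4,0.4,4.0,0.4
PlasmaSig01,0.4,0.4,0.4,4.0
PlasmaSig02,0.4,0.4,0.4,4.0
PlasmaSig03,0.4,0.4,0.4,4.0
PlasmaSig04,0.4,0.4,0.4,4.0
PlasmaSig05,0.4,0.4,0.4,4.0
PlasmaSig06,0.4,0.4,0.4,4.0
PlasmaSig07,0.4,0.4,0.4,4.0
PlasmaSig08,0.4,0.4,0.4,4.0
PlasmaSig09,0.4,0.4,0.4,4.0
PlasmaSig10,0.4,0.4,0.4,4.0
PlasmaSig11,0.4,0.4,0.4,4.0
PlasmaSig12,0.4,0.4,0.4,4.0
Gene0001,20.247,20.247,20.247,20.247
Gene0002,1.228,1.228,1.228,1.228
Gene0003,1.382,1.382,1.382,1.382
Gene0004,5.89,5.89,5.89,5.89
Gene0005,2.702,2.702,2.702,2.702
Gene0006,2.979,2.979,2.979,2.979
Gene0007,1.961,1.961,1.961,1.961
Gene0008,1.635,1.635,1.635,1.635
Gene0009,2.147,2.147,2.147,2.147
Gene0010,1.514,1.514,1.514,1.514
Gene0011,1.507,1.507,1.507,1.507
Gene0012,2.553,2.553,2.553,2.553
Gene0013,0.967,0.967,0.967,0.967
Gene0014,1.91,1.91,1.91,1.91
Gene0015,1.236,1.236,1.236,1.236
Gene0016,3.188,3.188,3.188,3.188
Gene0017,1.948,1.948,1.948,1.948
Gene0018,4.928,4.928,4.928,4.928
Gene0019,2.446,2.446,2.446,2.446
Gene0020,0.965,0.965,0.965,0.965
Gene0021,2.08,2.08,2.08,2.08
Gene0022,1.274,1.274,1.274,1.274
Gene0023,1.016,1.016,1.016,1.016
Gene0024,2.657,2.657,2.657,2.657
Gene0025,0.382,0.382,0.382,0.382
Gene0026,1.87,1.87,1.87,1.87
Gene0027,0.68,0.68,0.68,0.68
Gene0028,1.214,1.214,1.214,1.214
Gene0029,1.038,1.038,1.038,1.038
Gene0030,2.373,2.373,2.373,2.373
Gene0031,1.671,1.671,1.671,1.671
Gene0032,1.762,1.762,1.762,1.762
Gene0033,0.781,0.781,0.781,0.781
Gene0034,1.373,1.373,1.373,1.373
Gene0035,0.402,0.402,0.402,0.402
Gene0036,7.135,7.135,7.135,7.135
Gene0037,5.783,5.783,5.783,5.783
Gene0038,4.143,4.143,4.143,4.143
Gene0039,1.033,1.033,1.033,1.033
Gene0040,6.457,6.457,6.457,6.457
Gene0041,3.223,3.223,3.223,3.223
Gene0042,2.01,2.01,2.01,2.01
Gene0043,10.525,10.525,10.525,10.525
Gene0044,6.732,6.732,6.732,6.732
Gene0045,3.06,3.06,3.06,3.06
Gene0046,2.237,2.237,2.237,2.237
Gene0047,1.239,1.239,1.239,1.239
Gene0048,0.949,0.949,0.949,0.949
Gene0049,1.861,1.861,1.861,1.861
Gene0050,1.196,1.196,1.196,1.196
Gene0051,2.268,2.268,2.268,2.268
Gene0052,2.329,2.329,2.329,2.329
Gene0053,1.694,1.694,1.694,1.694
Gene0054,2.117,2.117,2.117,2.117
Gene0055,0.519,0.519,0.519,0.519
Gene0056,2.125,2.125,2.125,2.125
Gene0057,2.05,2.05,2.05,2.05
Gene0058,2.48,2.48,2.48,2.48
Gene0059,2.364,2.364,2.364,2.364
Gene0060,1.883,1.883,1.883,1.883
Gene0061,0.591,0.591,0.591,0.591
Gene0062,1.035,1.035,1.035,1.035
Gene0063,1.184,1.184,1.184,1.184
Gene0064,2.868,2.868,2.868,2.868
Gene0065,3.866,3.866,3.866,3.866
Gene0066,1.788,1.788,1.788,1.788
Gene0067,9.42,9.42,9.42,9.42
Gene0068,4.384,4.384,4.384,4.384
Gene0069,5.346,5.346,5.346,5.346
Gene0070,1.132,1.132,1.132,1.132
Gene0071,1.172,1.172,1.172,1.172
Gene0072,0.586,0.586,0.586,0.586
Gene0073,0.943,0.943,0.943,0.943
Gene0074,6.971,6.971,6.971,6.971
Gene0075,12.425,12.425,12.425,12.425
Gene0076,0.804,0.804,0.804,0.804
Gene0077,1.232,1.232,1.232,1.232
Gene0078,1.608,1.608,1.608,1.608
Gene0079,13.96,13.96,13.96,13.96
Gene0080,1.334,1.334,1.334,1.334
Gene0081,1.568,1.568,1.568,1.568
Gene0082,6.285,6.285,6.285,6.285
Gene0083,3.357,3.357,3.357,3.357
Gene0084,2.498,2.498,2.498,2.498
Gene0085,2.992,2.992,2.992,2.992
Gene0086,1.546,1.546,1.546,1.546
Gene0087,2.686,2.686,2.686,2.686
Gene0088,2.716,2.716,2.716,2.716
Gene0089,8.012,8.012,8.012,8.012
Gene0090,2.226,2.226,2.226,2.226
Gene0091,3.274,3.274,3.274,3.274
Gene0092,4.65,4.65,4.65,4.65
Gene0093,5.183,5.183,5.183,5.183
Gene0094,1.182,1.182,1.182,1.182
Gene0095,1.654,1.654,1.654,1.654
Gene0096,5.407,5.407,5.407,5.407
Gene0097,2.882,2.882,2.882,2.882
Gene0098,4.819,4.819,4.819,4.819
Gene0099,1.488,1.488,1.488,1.488
Gene0100,0.826,0.826,0.826,0.826
Gene0101,5.079,5.079,5.079,5.079
Gene0102,2.635,2.635,2.635,2.635
Gene0103,3.418,3.418,3.418,3.418
Gene0104,12.029,12.029,12.029,12.029
Gene0105,2.631,2.631,2.631,2.631
Gene0106,1.13,1.13,1.13,1.13
Gene0107,1.892,1.892,1.892,1.892
Gene0108,1.018,1.018,1.018,1.018
Gene0109,5.348,5.348,5.348,5.348
Gene0110,4.195,4.195,4.195,4.195
Gene0111,0.988,0.988,0.988,0.988
Gene0112,2.275,2.275,2.275,2.275
Gene0113,4.429,4.429,4.429,4.429
Gene0114,7.637,7.637,7.637,7.637
Gene0115,1.027,1.027,1.027,1.027
Gene0116,3.821,3.821,3.821,3.821
Gene0117,5.206,5.206,5.206,5.206
Gene0118,3.416,3.416,3.416,3.416
Gene0119,0.668,0.668,0.668,0.668
Gene0120,2.612,2.612,2.612,2.612
Gene0121,2.751,2.751,2.751,2.751
Gene0122,2.764,2.764,2.764,2.764
Gene0123,1.1,1.1,1.1,1.1
Gene0124,1.306,1.306,1.306,1.306
Gene0125,0.613,0.613,0.613,0.613
Gene0126,4.317,4.317,4.317,4.317
Gene0127,2.3,2.3,2.3,2.3
Gene0128,0.898,0.898,0.898,0.898
Gene0129,2.621,2.621,2.621,2.621
Gene0130,0.607,0.607,0.607,0.607
Gene0131,6.353,6.353,6.353,6.353
Gene0132,2.845,2.845,2.845,2.845
Gene0133,4.949,4.949,4.949,4.949
Gene0134,3.559,3.559,3.559,3.559
Gene0135,0.608,0.608,0.608,0.608
Gene0136,14.967,14.967,14.967,14.967
Gene0137,3.24,3.24,3.24,3.24
Gene0138,3.689,3.689,3.689,3.689
Gene0139,3.224,3.224,3.224,3.224
Gene0140,0.209,0.209,0.209,0.209
Gene0141,1.316,1.316,1.316,1.316
Gene0142,11.88,11.88,11.88,11.88
Gene0143,13.525,13.525,13.525,13.525
Gene0144,1.438,1.438,1.438,1.438
Gene0145,2.137,2.137,2.137,2.137
Gene0146,0.716,0.716,0.716,0.716
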