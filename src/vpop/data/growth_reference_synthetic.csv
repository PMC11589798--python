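sex,age_years,L,M,S,median_height_m
male,2.0,-2.0,16.6,0.08,0.87
male,2.25,-2.0,16.4551,0.08,0.8944
male,2.5,-2.0,16.3219,0.08,0.9177
male,2.75,-2.0,16.2027,0.08,0.9396
male,3.0,-2.0,16.1,0.08,0.96
male,3.25,-2.0,16.0145,0.08,0.9787
male,3.5,-2.0,15.9406,0.08,0.9961
male,3.75,-2.0,15.8715,0.08,1.0129
male,4.0,-2.0,15.8,0.08,1.03
male,4.25,-2.0,15.718,0.08027,1.0478
male,4.5,-2.0,15.6313,0.081,1.0657
male,4.75,-2.0,15.5539,0.08211,1.0833
male,5.0,-2.0,15.5,0.0835,1.1
male,5.25,-2.0,15.4633,0.08508,1.1156
male,5.5,-2.0,15.4313,0.08675,1.1306
male,5.75,-2.0,15.4086,0.08842,1.1452
male,6.0,-2.0,15.4,0.09,1.16
male,6.25,-2.0,15.4086,0.09159,1.175
male,6.5,-2.0,15.4313,0.09333,1.19
male,6.75,-2.0,15.4633,0.09519,1.205
male,7.0,-2.0,15.5,0.09713,1.22
male,7.25,-2.0,15.5519,0.09911,1.235
male,7.5,-2.0,15.6259,0.10111,1.25
male,7.75,-2.0,15.7119,0.10308,1.265
male,8.0,-2.0,15.8,0.105,1.28
male,8.25,-2.0,15.892,0.10692,1.2953
male,8.5,-2.0,15.9929,0.10889,1.3107
male,8.75,-2.0,16.0973,0.11089,1.3258
male,9.0,-2.0,16.2,0.11287,1.34
male,9.25,-2.0,16.2963,0.11481,1.3531
male,9.5,-2.0,16.39,0.11667,1.3656
male,9.75,-2.0,16.4887,0.11841,1.3777
male,10.0,-2.0,16.6,0.12,1.39
male,10.25,-2.0,16.7331,0.12149,1.4025
male,10.5,-2.0,16.885,0.12294,1.415
male,10.75,-2.0,17.0444,0.12434,1.4275
male,11.0,-2.0,17.2,0.12567,1.44
male,11.25,-2.0,17.35,0.12691,1.4521
male,11.5,-2.0,17.5,0.12806,1.464
male,11.75,-2.0,17.65,0.1291,1.4763
male,12.0,-2.0,17.8,0.13,1.49
male,12.25,-2.0,17.9478,0.13085,1.5056
male,12.5,-2.0,18.0942,0.13172,1.523
male,12.75,-2.0,18.2435,0.13256,1.5413
male,13.0,-2.0,18.4,0.13333,1.56
male,13.25,-2.0,18.57,0.134,1.5798
male,13.5,-2.0,18.75,0.13453,1.6008
male,13.75,-2.0,18.93,0.13488,1.6214
male,14.0,-2.0,19.1,0.135,1.64
male,14.25,-2.0,19.2565,0.135,1.6568
male,14.5,-2.0,19.4058,0.135,1.6726
male,14.75,-2.0,19.5522,0.135,1.6871
male,15.0,-2.0,19.7,0.135,1.7
male,15.25,-2.0,19.85,0.135,1.712
male,15.5,-2.0,20.0,0.135,1.7233
male,15.75,-2.0,20.15,0.135,1.7329
male,16.0,-2.0,20.3,0.135,1.74
male,16.25,-2.0,20.45,0.135,1.7448
male,16.5,-2.0,20.6,0.135,1.7487
male,16.75,-2.0,20.75,0.135,1.752
male,17.0,-2.0,20.9,0.135,1.755
male,17.25,-2.0,21.0526,0.135,1.7579
male,17.5,-2.0,21.2068,0.135,1.7607
male,17.75,-2.0,21.3577,0.135,1.7631
male,18.0,-2.0,21.5,0.135,1.765
male,18.25,-2.0,21.6314,0.135,1.7667
male,18.5,-2.0,21.7557,0.135,1.7683
male,18.75,-2.0,21.8771,0.135,1.7695
male,19.0,-2.0,22.0,0.135,1.77
male,19.25,-2.0,22.125,0.135,1.77
male,19.5,-2.0,22.25,0.135,1.77
male,19.75,-2.0,22.375,0.135,1.77
male,20.0,-2.0,22.5,0.135,1.77
female,2.0,-2.0,16.4,0.085,0.86
female,2.25,-2.0,16.2551,0.085,0.8844
female,2.5,-2.0,16.1219,0.085,0.9077
female,2.75,-2.0,16.0027,0.085,0.9296
female,3.0,-2.0,15.9,0.085,0.95
female,3.25,-2.0,15.8145,0.085,0.9687
female,3.5,-2.0,15.7406,0.085,0.9861
female,3.75,-2.0,15.6715,0.085,1.0029
female,4.0,-2.0,15.6,0.085,1.02
female,4.25,-2.0,15.518,0.08527,1.0378
female,4.5,-2.0,15.4312,0.086,1.0557
female,4.75,-2.0,15.3539,0.08711,1.0733
female,5.0,-2.0,15.3,0.0885,1.09
female,5.25,-2.0,15.2633,0.09008,1.1056
female,5.5,-2.0,15.2312,0.09175,1.1206
female,5.75,-2.0,15.2086,0.09342,1.1352
female,6.0,-2.0,15.2,0.095,1.15
female,6.25,-2.0,15.2188,0.09659,1.165
female,6.5,-2.0,15.2667,0.09833,1.18
female,6.75,-2.0,15.3313,0.10019,1.195
female,7.0,-2.0,15.4,0.10213,1.21
female,7.25,-2.0,15.4792,0.10411,1.225
female,7.5,-2.0,15.5778,0.10611,1.24
female,7.75,-2.0,15.6875,0.10808,1.255
female,8.0,-2.0,15.8,0.11,1.27
female,8.25,-2.0,15.9172,0.11192,1.2853
female,8.5,-2.0,16.0431,0.11389,1.3007
female,8.75,-2.0,16.1724,0.11589,1.3158
female,9.0,-2.0,16.3,0.11787,1.33
female,9.25,-2.0,16.4211,0.11981,1.3427
female,9.5,-2.0,16.5396,0.12167,1.3545
female,9.75,-2.0,16.6633,0.12341,1.3665
female,10.0,-2.0,16.8,0.125,1.38
female,10.25,-2.0,16.9586,0.12649,1.3961
female,10.5,-2.0,17.1354,0.12794,1.4142
female,10.75,-2.0,17.3195,0.12934,1.4327
female,11.0,-2.0,17.5,0.13067,1.45
female,11.25,-2.0,17.675,0.13191,1.4656
female,11.5,-2.0,17.85,0.13306,1.4806
female,11.75,-2.0,18.025,0.1341,1.4952
female,12.0,-2.0,18.2,0.135,1.51
female,12.25,-2.0,18.375,0.13585,1.5259
female,12.5,-2.0,18.55,0.13672,1.5425
female,12.75,-2.0,18.725,0.13756,1.5578
female,13.0,-2.0,18.9,0.13833,1.57
female,13.25,-2.0,19.0805,0.139,1.5792
female,13.5,-2.0,19.2646,0.13953,1.587
female,13.75,-2.0,19.4414,0.13988,1.5938
female,14.0,-2.0,19.6,0.14,1.6
female,14.25,-2.0,19.7367,0.14,1.606
female,14.5,-2.0,19.8604,0.14,1.6116
female,14.75,-2.0,19.9789,0.14,1.6164
female,15.0,-2.0,20.1,0.14,1.62
female,15.25,-2.0,20.2276,0.14,1.6226
female,15.5,-2.0,20.3569,0.14,1.6248
female,15.75,-2.0,20.4828,0.14,1.6265
female,16.0,-2.0,20.6,0.14,1.628
female,16.25,-2.0,20.7089,0.14,1.6292
female,16.5,-2.0,20.8127,0.14,1.6302
female,16.75,-2.0,20.9101,0.14,1.6311
female,17.0,-2.0,21.0,0.14,1.632
female,17.25,-2.0,21.0838,0.14,1.633
female,17.5,-2.0,21.1629,0.14,1.6339
female,17.75,-2.0,21.2354,0.14,1.6347
female,18.0,-2.0,21.3,0.14,1.635
female,18.25,-2.0,21.3556,0.14,1.635
female,18.5,-2.0,21.405,0.14,1.635
female,18.75,-2.0,21.4519,0.14,1.635
female,19.0,-2.0,21.5,0.14,1.635
female,19.25,-2.0,21.55,0.14,1.635
female,19.5,-2.0,21.6,0.14,1.635
female,19.75,-2.0,21.65,0.14,1.635
female,20.0,-2.0,21.7,0.14,1.635
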