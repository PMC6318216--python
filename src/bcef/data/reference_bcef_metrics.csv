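species,component,method,bcef,aic,se_pct,cvr_pct,fi,mep,mpe
C. mopane,stem,ratio,0.4517,36.4,147.5,62.7,0.4462,0.4436,1.3033
C. mopane,branches,ratio,0.3124,13.1,107.5,31.0,0.1514,0.1128,1.3817
C. mopane,foliage,ratio,0.0197,-42.4,333.0,286.3,0.0009,0.0043,0.0274
C. mopane,crown,ratio,0.3320,32.1,95.2,28.6,0.1670,0.2350,1.4062
C. mopane,agb,ratio,0.7837,37.7,88.3,31.9,1.0173,0.4787,2.6892
C. mopane,stem,ls,0.3206,9.9,64.9,27.1,0.1318,0.1054,0.2743
C. mopane,branches,ls,0.3498,10.1,4.5,26.7,0.0842,0.1252,0.2569
C. mopane,foliage,ls,0.0057,-91.2,13.9,64.5,0.0002,0.0003,0.0142
C. mopane,crown,ls,0.3556,11.0,4.6,26.9,0.0943,0.1326,0.2629
C. mopane,agb,ls,0.6762,27.7,3.9,22.4,0.3930,0.3474,0.4346
A. quanzensis,stem,ratio,0.6487,40.5,83.1,80.9,0.1952,0.2907,0.6347
A. quanzensis,branches,ratio,0.3174,-16.7,51.6,45.7,0.0523,0.0269,0.3080
A. quanzensis,foliage,ratio,0.0205,-118.2,96.4,87.6,0.0007,0.0009,0.0190
A. quanzensis,crown,ratio,0.3379,-13.8,51.6,45.7,0.0584,0.0363,0.3251
A. quanzensis,agb,ratio,0.9866,46.5,62.0,58.4,0.3820,0.4745,0.9221
A. quanzensis,stem,ls,0.4616,38.3,15.3,64.1,0.1789,0.1866,0.4485
A. quanzensis,branches,ls,0.2697,-17.6,10.3,33.1,0.0492,0.0174,0.1461
A. quanzensis,foliage,ls,0.0159,-118.0,14.7,74.3,0.0004,0.0004,0.0145
A. quanzensis,crown,ls,0.2856,-14.9,10.3,32.9,0.0548,0.0310,0.1533
A. quanzensis,agb,ls,0.7472,43.1,13.2,42.1,0.3408,0.3688,0.4770
M. stuhlmannii,stem,ratio,1.3581,36.4,56.1,58.7,0.4096,0.5802,0.7937
M. stuhlmannii,branches,ratio,0.3532,-8.6,48.1,269.8,0.3268,0.0288,0.2191
M. stuhlmannii,foliage,ratio,0.0234,-78.5,70.8,2092.9,0.0368,0.0003,0.0117
M. stuhlmannii,crown,ratio,0.3765,-6.7,48.0,55.1,0.0719,0.0327,0.2285
M. stuhlmannii,agb,ratio,1.7346,41.6,52.1,40.3,0.4235,0.8180,0.9934
M. stuhlmannii,stem,ls,0.7319,22.1,12.3,37.1,0.2507,0.2169,0.4162
M. stuhlmannii,branches,ls,0.2415,-14.9,14.4,38.0,0.0408,0.0208,0.1339
M. stuhlmannii,foliage,ls,0.0096,-93.8,13.1,54.6,0.0008,0.0000,0.0093
M. stuhlmannii,crown,ls,0.2511,-14.3,14.1,36.8,0.0429,0.0213,0.1349
M. stuhlmannii,agb,ls,0.9830,26.6,8.0,33.2,0.3265,0.2957,0.4662
P. angolensis,stem,ratio,0.4715,-30.6,21.8,46.6,0.0292,0.0185,0.1621
P. angolensis,branches,ratio,0.4231,-38.1,19.9,40.4,0.0292,0.0071,0.1699
P. angolensis,foliage,ratio,0.0240,-144.3,21.4,55.8,0.0003,0.0002,0.0074
P. angolensis,crown,ratio,0.4471,-38.3,18.7,38.4,0.0199,0.0070,0.1764
P. angolensis,agb,ratio,0.9186,-18.0,15.5,32.8,0.0585,0.0204,0.3160
P. angolensis,stem,ls,0.4634,-38.6,13.3,36.5,0.0242,0.0132,0.0922
P. angolensis,branches,ls,0.4748,-37.2,10.3,31.4,0.0182,0.0042,0.0745
P. angolensis,foliage,ls,0.0177,-147.3,15.3,42.8,0.0002,0.0000,0.0036
P. angolensis,crown,ls,0.4925,-9.2,10.0,33.8,0.0160,0.0052,0.0750
P. angolensis,agb,ls,0.9558,-26.2,8.9,29.1,0.0505,0.0168,0.1101
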