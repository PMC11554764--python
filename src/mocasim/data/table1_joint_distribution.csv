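sex,age_low,age_high,edu_years,edu_levels,status,percent
female,55,59,5,1,healthy,0.660
female,55,59,5,1,MCI,0.100
female,55,59,5,1,dementia,0.004
female,55,59,8,2,healthy,3.955
female,55,59,8,2,MCI,0.244
female,55,59,8,2,dementia,0.012
female,55,59,11,3,healthy,0.929
female,55,59,11,3,MCI,0.025
female,55,59,11,3,dementia,0.001
female,55,59,13,3,healthy,3.491
female,55,59,13,3,MCI,0.093
female,55,59,13,3,dementia,0.005
female,55,59,17,4,healthy,1.412
female,55,59,17,4,MCI,0.017
female,55,59,17,4,dementia,0.001
female,60,64,5,1,healthy,0.972
female,60,64,5,1,MCI,0.175
female,60,64,5,1,dementia,0.013
female,60,64,8,2,healthy,3.329
female,60,64,8,2,MCI,0.240
female,60,64,8,2,dementia,0.020
female,60,64,11,3,healthy,0.822
female,60,64,11,3,MCI,0.025
female,60,64,11,3,dementia,0.002
female,60,64,13,3,healthy,2.790
female,60,64,13,3,MCI,0.086
female,60,64,13,3,dementia,0.008
female,60,64,17,4,healthy,1.105
female,60,64,17,4,MCI,0.015
female,60,64,17,4,dementia,0.001
female,65,69,5,1,healthy,1.537
female,65,69,5,1,MCI,0.334
female,65,69,5,1,dementia,0.043
female,65,69,8,2,healthy,2.581
female,65,69,8,2,MCI,0.219
female,65,69,8,2,dementia,0.030
female,65,69,11,3,healthy,0.620
female,65,69,11,3,MCI,0.022
female,65,69,11,3,dementia,0.003
female,65,69,13,3,healthy,1.993
female,65,69,13,3,MCI,0.072
female,65,69,13,3,dementia,0.011
female,65,69,17,4,healthy,0.937
female,65,69,17,4,MCI,0.015
female,65,69,17,4,dementia,0.002
female,70,74,5,1,healthy,2.266
female,70,74,5,1,MCI,0.608
female,70,74,5,1,dementia,0.131
female,70,74,8,2,healthy,1.995
female,70,74,8,2,MCI,0.202
female,70,74,8,2,dementia,0.047
female,70,74,11,3,healthy,0.446
female,70,74,11,3,MCI,0.019
female,70,74,11,3,dementia,0.005
female,70,74,13,3,healthy,1.347
female,70,74,13,3,MCI,0.057
female,70,74,13,3,dementia,0.014
female,70,74,17,4,healthy,0.734
female,70,74,17,4,MCI,0.014
female,70,74,17,4,dementia,0.004
female,75,79,5,1,healthy,2.407
female,75,79,5,1,MCI,0.817
female,75,79,5,1,dementia,0.289
female,75,79,8,2,healthy,1.386
female,75,79,8,2,MCI,0.167
female,75,79,8,2,dementia,0.064
female,75,79,11,3,healthy,0.278
female,75,79,11,3,MCI,0.014
female,75,79,11,3,dementia,0.006
female,75,79,13,3,healthy,0.834
female,75,79,13,3,MCI,0.041
female,75,79,13,3,dementia,0.017
female,75,79,17,4,healthy,0.447
female,75,79,17,4,MCI,0.010
female,75,79,17,4,dementia,0.004
female,80,84,5,1,healthy,2.133
female,80,84,5,1,MCI,1.015
female,80,84,5,1,dementia,0.609
female,80,84,8,2,healthy,0.916
female,80,84,8,2,MCI,0.138
female,80,84,8,2,dementia,0.090
female,80,84,11,3,healthy,0.153
female,80,84,11,3,MCI,0.009
female,80,84,11,3,dementia,0.006
female,80,84,13,3,healthy,0.508
female,80,84,13,3,MCI,0.030
female,80,84,13,3,dementia,0.022
female,80,84,17,4,healthy,0.229
female,80,84,17,4,MCI,0.006
female,80,84,17,4,dementia,0.004
female,85,89,5,1,healthy,1.115
female,85,89,5,1,MCI,0.911
female,85,89,5,1,dementia,0.903
female,85,89,8,2,healthy,0.450
female,85,89,8,2,MCI,0.088
female,85,89,8,2,dementia,0.094
female,85,89,11,3,healthy,0.055
female,85,89,11,3,MCI,0.004
female,85,89,11,3,dementia,0.005
female,85,89,13,3,healthy,0.259
female,85,89,13,3,MCI,0.019
female,85,89,13,3,dementia,0.022
female,85,89,17,4,healthy,0.066
female,85,89,17,4,MCI,0.002
female,85,89,17,4,dementia,0.002
male,55,59,5,1,healthy,0.567
male,55,59,5,1,MCI,0.073
male,55,59,5,1,dementia,0.003
male,55,59,8,2,healthy,4.396
male,55,59,8,2,MCI,0.236
male,55,59,8,2,dementia,0.012
male,55,59,11,3,healthy,0.755
male,55,59,11,3,MCI,0.018
male,55,59,11,3,dementia,0.001
male,55,59,13,3,healthy,3.197
male,55,59,13,3,MCI,0.075
male,55,59,13,3,dementia,0.004
male,55,59,17,4,healthy,1.224
male,55,59,17,4,MCI,0.013
male,55,59,17,4,dementia,0.001
male,60,64,5,1,healthy,0.654
male,60,64,5,1,MCI,0.101
male,60,64,5,1,dementia,0.008
male,60,64,8,2,healthy,3.557
male,60,64,8,2,MCI,0.223
male,60,64,8,2,dementia,0.019
male,60,64,11,3,healthy,0.609
male,60,64,11,3,MCI,0.016
male,60,64,11,3,dementia,0.002
male,60,64,13,3,healthy,2.695
male,60,64,13,3,MCI,0.073
male,60,64,13,3,dementia,0.007
male,60,64,17,4,healthy,1.040
male,60,64,17,4,MCI,0.012
male,60,64,17,4,dementia,0.001
male,65,69,5,1,healthy,0.940
male,65,69,5,1,MCI,0.175
male,65,69,5,1,dementia,0.024
male,65,69,8,2,healthy,2.682
male,65,69,8,2,MCI,0.198
male,65,69,8,2,dementia,0.029
male,65,69,11,3,healthy,0.474
male,65,69,11,3,MCI,0.015
male,65,69,11,3,dementia,0.002
male,65,69,13,3,healthy,2.135
male,65,69,13,3,MCI,0.067
male,65,69,13,3,dementia,0.011
male,65,69,17,4,healthy,0.922
male,65,69,17,4,MCI,0.013
male,65,69,17,4,dementia,0.002
male,70,74,5,1,healthy,1.392
male,70,74,5,1,MCI,0.317
male,70,74,5,1,dementia,0.073
male,70,74,8,2,healthy,2.085
male,70,74,8,2,MCI,0.183
male,70,74,8,2,dementia,0.045
male,70,74,11,3,healthy,0.371
male,70,74,11,3,MCI,0.014
male,70,74,11,3,dementia,0.004
male,70,74,13,3,healthy,1.594
male,70,74,13,3,MCI,0.059
male,70,74,13,3,dementia,0.016
male,70,74,17,4,healthy,0.773
male,70,74,17,4,MCI,0.012
male,70,74,17,4,dementia,0.004
male,75,79,5,1,healthy,1.500
male,75,79,5,1,MCI,0.426
male,75,79,5,1,dementia,0.160
male,75,79,8,2,healthy,1.420
male,75,79,8,2,MCI,0.148
male,75,79,8,2,dementia,0.060
male,75,79,11,3,healthy,0.235
male,75,79,11,3,MCI,0.010
male,75,79,11,3,dementia,0.005
male,75,79,13,3,healthy,1.019
male,75,79,13,3,MCI,0.044
male,75,79,13,3,dementia,0.020
male,75,79,17,4,healthy,0.523
male,75,79,17,4,MCI,0.010
male,75,79,17,4,dementia,0.005
male,80,84,5,1,healthy,1.311
male,80,84,5,1,MCI,0.509
male,80,84,5,1,dementia,0.325
male,80,84,8,2,healthy,0.876
male,80,84,8,2,MCI,0.113
male,80,84,8,2,dementia,0.078
male,80,84,11,3,healthy,0.122
male,80,84,11,3,MCI,0.006
male,80,84,11,3,dementia,0.005
male,80,84,13,3,healthy,0.563
male,80,84,13,3,MCI,0.029
male,80,84,13,3,dementia,0.022
male,80,84,17,4,healthy,0.304
male,80,84,17,4,MCI,0.007
male,80,84,17,4,dementia,0.006
male,85,89,5,1,healthy,0.665
male,85,89,5,1,MCI,0.411
male,85,89,5,1,dementia,0.431
male,85,89,8,2,healthy,0.380
male,85,89,8,2,MCI,0.062
male,85,89,8,2,dementia,0.071
male,85,89,11,3,healthy,0.036
male,85,89,11,3,MCI,0.002
male,85,89,11,3,dementia,0.003
male,85,89,13,3,healthy,0.205
male,85,89,13,3,MCI,0.013
male,85,89,13,3,dementia,0.016
male,85,89,17,4,healthy,0.114
male,85,89,17,4,MCI,0.003
male,85,89,17,4,dementia,0.004
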