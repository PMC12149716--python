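# Synthetic restricted collision stopping power of polystyrene
# (computed from the ICRU-form restricted Moller formula, Z/A=0.53768,
#  I=68.7 eV, density 1.06 g/cm^3, cutoff Delta=1 keV; no density effect).
energy_MeV,L_delta_MeV_per_cm
0.001,126.886
0.00108047,120.671
0.00116742,114.681
0.00126136,108.918
0.00136287,103.38
0.00147254,98.066
0.00159104,92.9737
0.00171907,88.0995
0.00185741,83.4391
0.00200688,78.9496
0.00216838,73.9586
0.00234287,69.3427
0.0025314,65.042
0.00273511,61.0173
0.00295521,57.2411
0.00319302,53.6931
0.00344997,50.3572
0.00372759,47.22
0.00402756,44.2697
0.00435167,41.4958
0.00470185,38.8884
0.00508022,36.4385
0.00548903,34.1375
0.00593074,31.9772
0.006408,29.9497
0.00692367,28.0478
0.00748083,26.2643
0.00808282,24.5924
0.00873326,23.0257
0.00943604,21.5581
0.0101954,20.1837
0.0110158,18.8971
0.0119023,17.6929
0.0128601,16.5662
0.013895,15.5123
0.0150131,14.5267
0.0162212,13.6052
0.0175266,12.7439
0.018937,11.939
0.0204609,11.1869
0.0221074,10.4844
0.0238864,9.82829
0.0258086,9.21568
0.0278855,8.64377
0.0301295,8.10997
0.0325541,7.61185
0.0351737,7.14711
0.0380042,6.71361
0.0410625,6.30932
0.0443669,5.93237
0.0479372,5.58098
0.0517947,5.25349
0.0559628,4.94836
0.0604662,4.66412
0.065332,4.39943
0.0705894,4.153
0.0762699,3.92365
0.0824074,3.71026
0.0890389,3.5118
0.096204,3.3273
0.103946,3.15584
0.11231,2.99657
0.121348,2.84872
0.131113,2.71153
0.141664,2.58432
0.153064,2.46644
0.165382,2.35729
0.17869,2.25631
0.19307,2.16298
0.208606,2.07681
0.225393,1.99734
0.243531,1.92415
0.263129,1.85685
0.284303,1.79505
0.307181,1.73842
0.331901,1.68663
0.35861,1.63937
0.387468,1.59637
0.418648,1.55737
0.452337,1.5221
0.488737,1.49035
0.528067,1.46188
0.570562,1.43649
0.616476,1.414
0.666085,1.39421
0.719686,1.37696
0.7776,1.36207
0.840175,1.34941
0.907785,1.33881
0.980837,1.33015
1.05977,1.32328
1.14505,1.3181
1.23719,1.31447
1.33675,1.31229
1.44432,1.31145
1.56055,1.31186
1.68613,1.31342
1.82181,1.31604
1.96842,1.31963
2.12682,1.32413
2.29797,1.32945
2.48289,1.33553
2.6827,1.3423
2.89858,1.3497
3.13183,1.35769
3.38386,1.3662
3.65616,1.37519
3.95038,1.38461
4.26827,1.39444
4.61175,1.40462
4.98286,1.41512
5.38384,1.42592
5.81709,1.43699
6.2852,1.44829
6.79099,1.45981
7.33747,1.47153
7.92793,1.48343
8.5659,1.49548
9.25522,1.50767
10,1.52
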