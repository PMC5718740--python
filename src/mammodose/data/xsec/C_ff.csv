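# element=C squared IT92 form factor vs x^2 (1/A^2)
x2_invA2,F2
0.000000e+00,3.599040e+01
1.000000e-03,3.477013e+01
1.107398e-03,3.464265e+01
1.226331e-03,3.450227e+01
1.358036e-03,3.434778e+01
1.503887e-03,3.417786e+01
1.665402e-03,3.399111e+01
1.844263e-03,3.378604e+01
2.042333e-03,3.356103e+01
2.261676e-03,3.331440e+01
2.504576e-03,3.304435e+01
2.773563e-03,3.274900e+01
3.071438e-03,3.242642e+01
3.401305e-03,3.207459e+01
3.766599e-03,3.169146e+01
4.171125e-03,3.127497e+01
4.619096e-03,3.082308e+01
5.115178e-03,3.033379e+01
5.664539e-03,2.980521e+01
6.272900e-03,2.923562e+01
6.946598e-03,2.862350e+01
7.692650e-03,2.796763e+01
8.518826e-03,2.726716e+01
9.433732e-03,2.652170e+01
1.044690e-02,2.573137e+01
1.156888e-02,2.489696e+01
1.281135e-02,2.401993e+01
1.418727e-02,2.310254e+01
1.571095e-02,2.214789e+01
1.739828e-02,2.115997e+01
1.926682e-02,2.014363e+01
2.133605e-02,1.910460e+01
2.362750e-02,1.804940e+01
2.616505e-02,1.698525e+01
2.897512e-02,1.591988e+01
3.208700e-02,1.486139e+01
3.553308e-02,1.381799e+01
3.934927e-02,1.279778e+01
4.357531e-02,1.180851e+01
4.825522e-02,1.085733e+01
5.343774e-02,9.950580e+00
5.917686e-02,9.093656e+00
6.553234e-02,8.290846e+00
7.257040e-02,7.545285e+00
8.036432e-02,6.858926e+00
8.899530e-02,6.232559e+00
9.855324e-02,5.665857e+00
1.091377e-01,5.157450e+00
1.208589e-01,4.705013e+00
1.338389e-01,4.305375e+00
1.482129e-01,3.954639e+00
1.641307e-01,3.648330e+00
1.817581e-01,3.381558e+00
2.012785e-01,3.149199e+00
2.228955e-01,2.946082e+00
2.468340e-01,2.767167e+00
2.733436e-01,2.607699e+00
3.027002e-01,2.463332e+00
3.352096e-01,2.330202e+00
3.712105e-01,2.204965e+00
4.110778e-01,2.084800e+00
4.552268e-01,1.967397e+00
5.041174e-01,1.850945e+00
5.582586e-01,1.734121e+00
6.182146e-01,1.616082e+00
6.846097e-01,1.496458e+00
7.581355e-01,1.375325e+00
8.395579e-01,1.253159e+00
9.297248e-01,1.130783e+00
1.029576e+00,1.009294e+00
1.140150e+00,8.899829e-01
1.262600e+00,7.742651e-01
1.398201e+00,6.635987e-01
1.548365e+00,5.594083e-01
1.714657e+00,4.630056e-01
1.898808e+00,3.755103e-01
2.102736e+00,2.977748e-01
2.328566e+00,2.303220e-01
2.578650e+00,1.733016e-01
2.855592e+00,1.264743e-01
3.162278e+00,8.922981e-02
3.501900e+00,6.063839e-02
3.877998e+00,3.953375e-02
4.294488e+00,2.461705e-02
4.755708e+00,1.456829e-02
5.266462e+00,8.149165e-03
5.832071e+00,4.282738e-03
6.458424e+00,2.100505e-03
7.152047e+00,9.543271e-04
7.920164e+00,3.983578e-04
8.770775e+00,1.513909e-04
9.712740e+00,5.185620e-05
1.075587e+01,1.583176e-05
1.191103e+01,4.255184e-06
1.319025e+01,9.931734e-07
1.460686e+01,1.982748e-07
1.617561e+01,3.329335e-08
1.791284e+01,4.615550e-09
1.983665e+01,5.175203e-10
2.196707e+01,4.587449e-11
2.432629e+01,3.134686e-12
2.693889e+01,1.605674e-13
2.983208e+01,5.977500e-15
3.303599e+01,1.562770e-16
3.658400e+01,2.762481e-18
4.051305e+01,3.165762e-20
4.486408e+01,2.245001e-22
4.968240e+01,9.356813e-25
5.501819e+01,2.164823e-27
6.092705e+01,2.610037e-30
6.747050e+01,1.528974e-33
7.471671e+01,4.027318e-37
8.274114e+01,4.377364e-41
9.162739e+01,1.785271e-45
1.014680e+02,2.459068e-50
1.123655e+02,1.018079e-55
1.244333e+02,1.113447e-61
1.377972e+02,2.788335e-68
1.525964e+02,1.364741e-75
1.689850e+02,1.095578e-83
1.871337e+02,1.187968e-92
2.072315e+02,1.403328e-102
2.294877e+02,1.423319e-113
2.541343e+02,9.521946e-126
2.814279e+02,3.137776e-139
3.116527e+02,3.686082e-154
3.451236e+02,1.079065e-170
3.821893e+02,5.294934e-189
4.232357e+02,2.807376e-209
4.686904e+02,9.889695e-232
5.190269e+02,1.350957e-256
5.747694e+02,3.941798e-284
6.364986e+02,1.269242e-314
7.048574e+02,0.000000e+00
7.805578e+02,0.000000e+00
8.643883e+02,0.000000e+00
9.572220e+02,0.000000e+00
1.060026e+03,0.000000e+00
1.173871e+03,0.000000e+00
1.299942e+03,0.000000e+00
1.439554e+03,0.000000e+00
1.594159e+03,0.000000e+00
1.765369e+03,0.000000e+00
1.954966e+03,0.000000e+00
2.164926e+03,0.000000e+00
2.397435e+03,0.000000e+00
2.654915e+03,0.000000e+00
2.940048e+03,0.000000e+00
3.255804e+03,0.000000e+00
3.605471e+03,0.000000e+00
3.992692e+03,0.000000e+00
4.421500e+03,0.000000e+00
4.896361e+03,0.000000e+00
5.422221e+03,0.000000e+00
6.004558e+03,0.000000e+00
6.649436e+03,0.000000e+00
7.363573e+03,0.000000e+00
8.154407e+03,0.000000e+00
9.030176e+03,0.000000e+00
1.000000e+04,0.000000e+00
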