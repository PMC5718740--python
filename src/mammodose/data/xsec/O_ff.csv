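# element=O squared IT92 form factor vs x^2 (1/A^2)
x2_invA2,F2
0.000000e+00,6.399040e+01
1.000000e-03,6.268748e+01
1.107398e-03,6.254978e+01
1.226331e-03,6.239779e+01
1.358036e-03,6.223008e+01
1.503887e-03,6.204510e+01
1.665402e-03,6.184116e+01
1.844263e-03,6.161642e+01
2.042333e-03,6.136889e+01
2.261676e-03,6.109640e+01
2.504576e-03,6.079665e+01
2.773563e-03,6.046712e+01
3.071438e-03,6.010515e+01
3.401305e-03,5.970786e+01
3.766599e-03,5.927224e+01
4.171125e-03,5.879506e+01
4.619096e-03,5.827297e+01
5.115178e-03,5.770244e+01
5.664539e-03,5.707985e+01
6.272900e-03,5.640147e+01
6.946598e-03,5.566353e+01
7.692650e-03,5.486228e+01
8.518826e-03,5.399400e+01
9.433732e-03,5.305517e+01
1.044690e-02,5.204249e+01
1.156888e-02,5.095299e+01
1.281135e-02,4.978421e+01
1.418727e-02,4.853427e+01
1.571095e-02,4.720207e+01
1.739828e-02,4.578738e+01
1.926682e-02,4.429107e+01
2.133605e-02,4.271522e+01
2.362750e-02,4.106327e+01
2.616505e-02,3.934013e+01
2.897512e-02,3.755229e+01
3.208700e-02,3.570782e+01
3.553308e-02,3.381642e+01
3.934927e-02,3.188927e+01
4.357531e-02,2.993894e+01
4.825522e-02,2.797911e+01
5.343774e-02,2.602433e+01
5.917686e-02,2.408963e+01
6.553234e-02,2.219015e+01
7.257040e-02,2.034066e+01
8.036432e-02,1.855519e+01
8.899530e-02,1.684660e+01
9.855324e-02,1.522619e+01
1.091377e-01,1.370343e+01
1.208589e-01,1.228569e+01
1.338389e-01,1.097811e+01
1.482129e-01,9.783497e+00
1.641307e-01,8.702336e+00
1.817581e-01,7.732892e+00
2.012785e-01,6.871370e+00
2.228955e-01,6.112186e+00
2.468340e-01,5.448294e+00
2.733436e-01,4.871583e+00
3.027002e-01,4.373300e+00
3.352096e-01,3.944454e+00
3.712105e-01,3.576179e+00
4.110778e-01,3.260017e+00
4.552268e-01,2.988098e+00
5.041174e-01,2.753223e+00
5.582586e-01,2.548869e+00
6.182146e-01,2.369145e+00
6.846097e-01,2.208746e+00
7.581355e-01,2.062922e+00
8.395579e-01,1.927493e+00
9.297248e-01,1.798907e+00
1.029576e+00,1.674309e+00
1.140150e+00,1.551602e+00
1.262600e+00,1.429464e+00
1.398201e+00,1.307315e+00
1.548365e+00,1.185226e+00
1.714657e+00,1.063798e+00
1.898808e+00,9.440222e-01
2.102736e+00,8.271471e-01
2.328566e+00,7.145606e-01
2.578650e+00,6.076850e-01
2.855592e+00,5.078833e-01
3.162278e+00,4.163726e-01
3.501900e+00,3.341442e-01
3.877998e+00,2.618932e-01
4.294488e+00,1.999634e-01
4.755708e+00,1.483176e-01
5.266462e+00,1.065367e-01
5.832071e+00,7.385387e-02
6.458424e+00,4.922179e-02
7.152047e+00,3.140627e-02
7.920164e+00,1.909490e-02
8.770775e+00,1.100551e-02
9.712740e+00,5.978625e-03
1.075587e+01,3.041804e-03
1.191103e+01,1.439272e-03
1.319025e+01,6.284223e-04
1.460686e+01,2.510201e-04
1.617561e+01,9.085789e-05
1.791284e+01,2.948608e-05
1.983665e+01,8.479712e-06
2.196707e+01,2.133130e-06
2.432629e+01,4.626825e-07
2.693889e+01,8.516575e-08
2.983208e+01,1.307095e-08
3.303599e+01,1.640333e-09
3.658400e+01,1.647217e-10
4.051305e+01,1.292310e-11
4.486408e+01,7.713761e-13
4.968240e+01,3.401729e-14
5.501819e+01,1.072872e-15
6.092705e+01,2.334399e-17
6.747050e+01,3.367181e-19
7.471671e+01,3.080688e-21
8.274114e+01,1.702492e-23
9.162739e+01,5.383494e-26
1.014680e+02,9.173728e-29
1.123655e+02,7.883039e-32
1.244333e+02,3.173764e-35
1.377972e+02,5.518564e-39
1.525964e+02,3.786931e-43
1.689850e+02,9.280949e-48
1.871337e+02,7.273060e-53
2.072315e+02,1.612428e-58
2.294877e+02,8.830574e-65
2.541343e+02,1.028075e-71
2.814279e+02,2.154596e-79
3.116527e+02,6.761341e-88
3.451236e+02,2.590941e-97
3.821893e+02,9.672962e-108
4.232357e+02,2.739835e-119
4.686904e+02,4.463473e-132
5.190269e+02,3.077573e-146
5.747694e+02,6.394823e-162
6.364986e+02,2.749096e-179
7.048574e+02,1.612153e-198
7.805578e+02,8.131387e-220
8.643883e+02,2.116598e-243
9.572220e+02,1.615018e-269
1.060026e+03,1.930852e-298
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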