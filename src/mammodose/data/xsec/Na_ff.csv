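# element=Na squared IT92 form factor vs x^2 (1/A^2)
x2_invA2,F2
0.000000e+00,1.208329e+02
1.000000e-03,1.169240e+02
1.107398e-03,1.165303e+02
1.226331e-03,1.160998e+02
1.358036e-03,1.156298e+02
1.503887e-03,1.151173e+02
1.665402e-03,1.145594e+02
1.844263e-03,1.139531e+02
2.042333e-03,1.132955e+02
2.261676e-03,1.125836e+02
2.504576e-03,1.118148e+02
2.773563e-03,1.109864e+02
3.071438e-03,1.100962e+02
3.401305e-03,1.091423e+02
3.766599e-03,1.081232e+02
4.171125e-03,1.070379e+02
4.619096e-03,1.058863e+02
5.115178e-03,1.046687e+02
5.664539e-03,1.033862e+02
6.272900e-03,1.020408e+02
6.946598e-03,1.006353e+02
7.692650e-03,9.917289e+01
8.518826e-03,9.765774e+01
9.433732e-03,9.609420e+01
1.044690e-02,9.448680e+01
1.156888e-02,9.283989e+01
1.281135e-02,9.115722e+01
1.418727e-02,8.944157e+01
1.571095e-02,8.769423e+01
1.739828e-02,8.591470e+01
1.926682e-02,8.410030e+01
2.133605e-02,8.224603e+01
2.362750e-02,8.034460e+01
2.616505e-02,7.838663e+01
2.897512e-02,7.636124e+01
3.208700e-02,7.425668e+01
3.553308e-02,7.206134e+01
3.934927e-02,6.976469e+01
4.357531e-02,6.735830e+01
4.825522e-02,6.483670e+01
5.343774e-02,6.219807e+01
5.917686e-02,5.944462e+01
6.553234e-02,5.658279e+01
7.257040e-02,5.362316e+01
8.036432e-02,5.058027e+01
8.899530e-02,4.747227e+01
9.855324e-02,4.432056e+01
1.091377e-01,4.114919e+01
1.208589e-01,3.798435e+01
1.338389e-01,3.485355e+01
1.482129e-01,3.178480e+01
1.641307e-01,2.880562e+01
1.817581e-01,2.594202e+01
2.012785e-01,2.321749e+01
2.228955e-01,2.065205e+01
2.468340e-01,1.826157e+01
2.733436e-01,1.605722e+01
3.027002e-01,1.404530e+01
3.352096e-01,1.222736e+01
3.712105e-01,1.060054e+01
4.110778e-01,9.158289e+00
4.552268e-01,7.891004e+00
5.041174e-01,6.786903e+00
5.582586e-01,5.832735e+00
6.182146e-01,5.014426e+00
6.846097e-01,4.317566e+00
7.581355e-01,3.727780e+00
8.395579e-01,3.230985e+00
9.297248e-01,2.813598e+00
1.029576e+00,2.462719e+00
1.140150e+00,2.166326e+00
1.262600e+00,1.913482e+00
1.398201e+00,1.694547e+00
1.548365e+00,1.501373e+00
1.714657e+00,1.327447e+00
1.898808e+00,1.167947e+00
2.102736e+00,1.019691e+00
2.328566e+00,8.809463e-01
2.578650e+00,7.511517e-01
2.855592e+00,6.305660e-01
3.162278e+00,5.199120e-01
3.501900e+00,4.200567e-01
3.877998e+00,3.317565e-01
4.294488e+00,2.554801e-01
4.755708e+00,1.913027e-01
5.266462e+00,1.388659e-01
5.832071e+00,9.739342e-02
6.458424e+00,6.575328e-02
7.152047e+00,4.255806e-02
7.920164e+00,2.628784e-02
8.770775e+00,1.541904e-02
9.712740e+00,8.540356e-03
1.075587e+01,4.439542e-03
1.191103e+01,2.151219e-03
1.319025e+01,9.643566e-04
1.460686e+01,3.966142e-04
1.617561e+01,1.482713e-04
1.791284e+01,4.987164e-05
1.983665e+01,1.492207e-05
2.196707e+01,3.922157e-06
2.432629e+01,8.930944e-07
2.693889e+01,1.734814e-07
2.983208e+01,2.826044e-08
3.303599e+01,3.788500e-09
3.658400e+01,4.092871e-10
4.051305e+01,3.481730e-11
4.486408e+01,2.273113e-12
4.968240e+01,1.107035e-13
5.501819e+01,3.897141e-15
6.092705e+01,9.577159e-17
6.747050e+01,1.580771e-18
7.471671e+01,1.679106e-20
8.274114e+01,1.094727e-22
9.162739e+01,4.157052e-25
1.014680e+02,8.675726e-28
1.123655e+02,9.331417e-31
1.244333e+02,4.817183e-34
1.377972e+02,1.103073e-37
1.525964e+02,1.026753e-41
1.689850e+02,3.526880e-46
1.871337e+02,4.016817e-51
2.072315e+02,1.347254e-56
2.294877e+02,1.167006e-62
2.541343e+02,2.257401e-69
2.814279e+02,8.301002e-77
3.116527e+02,4.855155e-85
3.451236e+02,3.707442e-94
3.821893e+02,2.970180e-104
4.232357e+02,1.959603e-115
4.686904e+02,8.142840e-128
5.190269e+02,1.583598e-141
5.747694e+02,1.037442e-156
6.364986e+02,1.590682e-173
7.048574e+02,3.813900e-192
7.805578e+02,9.149104e-213
8.643883e+02,1.339179e-235
9.572220e+02,6.916897e-261
1.060026e+03,6.874078e-289
1.173871e+03,6.715340e-320
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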