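# element=H squared IT92 form factor vs x^2 (1/A^2)
x2_invA2,F2
0.000000e+00,9.999060e-01
1.000000e-03,9.677245e-01
1.107398e-03,9.643466e-01
1.226331e-03,9.606233e-01
1.358036e-03,9.565213e-01
1.503887e-03,9.520046e-01
1.665402e-03,9.470341e-01
1.844263e-03,9.415681e-01
2.042333e-03,9.355614e-01
2.261676e-03,9.289660e-01
2.504576e-03,9.217307e-01
2.773563e-03,9.138011e-01
3.071438e-03,9.051203e-01
3.401305e-03,8.956282e-01
3.766599e-03,8.852629e-01
4.171125e-03,8.739605e-01
4.619096e-03,8.616559e-01
5.115178e-03,8.482838e-01
5.664539e-03,8.337796e-01
6.272900e-03,8.180807e-01
6.946598e-03,8.011282e-01
7.692650e-03,7.828684e-01
8.518826e-03,7.632551e-01
9.433732e-03,7.422521e-01
1.044690e-02,7.198352e-01
1.156888e-02,6.959957e-01
1.281135e-02,6.707427e-01
1.418727e-02,6.441065e-01
1.571095e-02,6.161410e-01
1.739828e-02,5.869268e-01
1.926682e-02,5.565728e-01
2.133605e-02,5.252178e-01
2.362750e-02,4.930315e-01
2.616505e-02,4.602130e-01
2.897512e-02,4.269899e-01
3.208700e-02,3.936145e-01
3.553308e-02,3.603588e-01
3.934927e-02,3.275085e-01
4.357531e-02,2.953549e-01
4.825522e-02,2.641864e-01
5.343774e-02,2.342787e-01
5.917686e-02,2.058853e-01
6.553234e-02,1.792284e-01
7.257040e-02,1.544901e-01
8.036432e-02,1.318068e-01
8.899530e-02,1.112644e-01
9.855324e-02,9.289683e-02
1.091377e-01,7.668746e-02
1.208589e-01,6.257292e-02
1.338389e-01,5.044930e-02
1.482129e-01,4.018009e-02
1.641307e-01,3.160479e-02
1.817581e-01,2.454776e-02
2.012785e-01,1.882632e-02
2.228955e-01,1.425787e-02
2.468340e-01,1.066588e-02
2.733436e-01,7.884609e-03
3.027002e-01,5.762816e-03
3.352096e-01,4.166462e-03
3.712105e-01,2.980292e-03
4.110778e-01,2.108305e-03
4.552268e-01,1.473082e-03
5.041174e-01,1.014103e-03
5.582586e-01,6.853306e-04
6.182146e-01,4.524454e-04
6.846097e-01,2.900890e-04
7.581355e-01,1.794437e-04
8.395579e-01,1.063374e-04
9.297248e-01,5.992562e-05
1.029576e+00,3.187380e-05
1.140150e+00,1.587763e-05
1.262600e+00,7.348002e-06
1.398201e+00,3.132459e-06
1.548365e+00,1.218869e-06
1.714657e+00,4.286021e-07
1.898808e+00,1.347168e-07
2.102736e+00,3.739501e-08
2.328566e+00,9.045413e-09
2.578650e+00,1.878646e-09
2.855592e+00,3.295744e-10
3.162278e+00,4.796015e-11
3.501900e+00,5.674237e-12
3.877998e+00,5.338009e-13
4.294488e+00,3.895865e-14
4.755708e+00,2.146549e-15
5.266462e+00,8.663198e-17
5.832071e+00,2.476828e-18
6.458424e+00,4.834084e-20
7.152047e+00,6.181964e-22
7.920164e+00,4.950100e-24
8.770775e+00,2.360151e-26
9.712740e+00,6.337561e-29
1.075587e+01,9.011186e-32
1.191103e+01,6.336714e-35
1.319025e+01,2.043284e-38
1.460686e+01,2.778490e-42
1.617561e+01,1.452218e-46
1.791284e+01,2.632690e-51
1.983665e+01,1.477492e-56
2.196707e+01,2.263166e-62
2.432629e+01,8.230153e-69
2.693889e+01,6.088768e-76
2.983208e+01,7.723386e-84
3.303599e+01,1.389929e-92
3.658400e+01,2.877402e-102
4.051305e+01,5.432073e-113
4.486408e+01,7.230843e-125
4.968240e+01,5.104764e-138
5.501819e+01,1.394268e-152
6.092705e+01,1.038987e-168
6.747050e+01,1.434778e-186
7.471671e+01,2.392471e-206
8.274114e+01,2.997745e-228
9.162739e+01,1.669178e-252
1.014680e+02,2.308576e-279
1.123655e+02,4.164487e-309
1.244333e+02,0.000000e+00
1.377972e+02,0.000000e+00
1.525964e+02,0.000000e+00
1.689850e+02,0.000000e+00
1.871337e+02,0.000000e+00
2.072315e+02,0.000000e+00
2.294877e+02,0.000000e+00
2.541343e+02,0.000000e+00
2.814279e+02,0.000000e+00
3.116527e+02,0.000000e+00
3.451236e+02,0.000000e+00
3.821893e+02,0.000000e+00
4.232357e+02,0.000000e+00
4.686904e+02,0.000000e+00
5.190269e+02,0.000000e+00
5.747694e+02,0.000000e+00
6.364986e+02,0.000000e+00
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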