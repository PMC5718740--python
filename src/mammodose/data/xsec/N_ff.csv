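# element=N squared IT92 form factor vs x^2 (1/A^2)
x2_invA2,F2
0.000000e+00,4.892443e+01
1.000000e-03,4.768679e+01
1.107398e-03,4.755642e+01
1.226331e-03,4.741262e+01
1.358036e-03,4.725407e+01
1.503887e-03,4.707934e+01
1.665402e-03,4.688687e+01
1.844263e-03,4.667499e+01
2.042333e-03,4.644188e+01
2.261676e-03,4.618560e+01
2.504576e-03,4.590405e+01
2.773563e-03,4.559501e+01
3.071438e-03,4.525611e+01
3.401305e-03,4.488485e+01
3.766599e-03,4.447860e+01
4.171125e-03,4.403461e+01
4.619096e-03,4.355007e+01
5.115178e-03,4.302205e+01
5.664539e-03,4.244764e+01
6.272900e-03,4.182389e+01
6.946598e-03,4.114796e+01
7.692650e-03,4.041709e+01
8.518826e-03,3.962876e+01
9.433732e-03,3.878072e+01
1.044690e-02,3.787113e+01
1.156888e-02,3.689864e+01
1.281135e-02,3.586254e+01
1.418727e-02,3.476288e+01
1.571095e-02,3.360060e+01
1.739828e-02,3.237767e+01
1.926682e-02,3.109721e+01
2.133605e-02,2.976358e+01
2.362750e-02,2.838245e+01
2.616505e-02,2.696084e+01
2.897512e-02,2.550710e+01
3.208700e-02,2.403080e+01
3.553308e-02,2.254260e+01
3.934927e-02,2.105398e+01
4.357531e-02,1.957698e+01
4.825522e-02,1.812380e+01
5.343774e-02,1.670643e+01
5.917686e-02,1.533616e+01
6.553234e-02,1.402325e+01
7.257040e-02,1.277650e+01
8.036432e-02,1.160303e+01
8.899530e-02,1.050803e+01
9.855324e-02,9.494819e+00
1.091377e-01,8.564824e+00
1.208589e-01,7.717825e+00
1.338389e-01,6.952195e+00
1.482129e-01,6.265198e+00
1.641307e-01,5.653277e+00
1.817581e-01,5.112297e+00
2.012785e-01,4.637718e+00
2.228955e-01,4.224690e+00
2.468340e-01,3.868092e+00
2.733436e-01,3.562534e+00
3.027002e-01,3.302353e+00
3.352096e-01,3.081644e+00
3.712105e-01,2.894333e+00
4.110778e-01,2.734317e+00
4.552268e-01,2.595641e+00
5.041174e-01,2.472724e+00
5.582586e-01,2.360580e+00
6.182146e-01,2.255006e+00
6.846097e-01,2.152713e+00
7.581355e-01,2.051355e+00
8.395579e-01,1.949488e+00
9.297248e-01,1.846439e+00
1.029576e+00,1.742150e+00
1.140150e+00,1.637012e+00
1.262600e+00,1.531720e+00
1.398201e+00,1.427159e+00
1.548365e+00,1.324322e+00
1.714657e+00,1.224245e+00
1.898808e+00,1.127954e+00
2.102736e+00,1.036419e+00
2.328566e+00,9.505134e-01
2.578650e+00,8.709723e-01
2.855592e+00,7.983607e-01
3.162278e+00,7.330507e-01
3.501900e+00,6.752092e-01
3.877998e+00,6.247980e-01
4.294488e+00,5.815847e-01
4.755708e+00,5.451630e-01
5.266462e+00,5.149790e-01
5.832071e+00,4.903629e-01
6.458424e+00,4.705622e-01
7.152047e+00,4.547781e-01
7.920164e+00,4.422015e-01
8.770775e+00,4.320507e-01
9.712740e+00,4.236055e-01
1.075587e+01,4.162357e-01
1.191103e+01,4.094194e-01
1.319025e+01,4.027486e-01
1.460686e+01,3.959228e-01
1.617561e+01,3.887323e-01
1.791284e+01,3.810365e-01
1.983665e+01,3.727431e-01
2.196707e+01,3.637900e-01
2.432629e+01,3.541334e-01
2.693889e+01,3.437408e-01
2.983208e+01,3.325882e-01
3.303599e+01,3.206597e-01
3.658400e+01,3.079487e-01
4.051305e+01,2.944596e-01
4.486408e+01,2.802102e-01
4.968240e+01,2.652337e-01
5.501819e+01,2.495809e-01
6.092705e+01,2.333227e-01
6.747050e+01,2.165512e-01
7.471671e+01,1.993815e-01
8.274114e+01,1.819518e-01
9.162739e+01,1.644223e-01
1.014680e+02,1.469740e-01
1.123655e+02,1.298038e-01
1.244333e+02,1.131202e-01
1.377972e+02,9.713504e-02
1.525964e+02,8.205515e-02
1.689850e+02,6.807172e-02
1.871337e+02,5.534946e-02
2.072315e+02,4.401594e-02
2.294877e+02,3.415231e-02
2.541343e+02,2.578672e-02
2.814279e+02,1.889152e-02
3.116527e+02,1.338520e-02
3.451236e+02,9.139278e-03
3.821893e+02,5.989650e-03
4.232357e+02,3.751305e-03
4.686904e+02,2.234282e-03
5.190269e+02,1.258706e-03
5.747694e+02,6.667227e-04
6.364986e+02,3.298578e-04
7.048574e+02,1.513162e-04
7.805578e+02,6.384045e-05
8.643883e+02,2.455019e-05
9.572220e+02,8.519992e-06
1.060026e+03,2.639135e-06
1.173871e+03,7.208099e-07
1.299942e+03,1.712561e-07
1.439554e+03,3.486871e-08
1.594159e+03,5.983994e-09
1.765369e+03,8.498436e-10
1.954966e+03,9.787023e-11
2.164926e+03,8.936116e-12
2.397435e+03,6.309667e-13
2.654915e+03,3.351456e-14
2.940048e+03,1.298830e-15
3.255804e+03,3.550251e-17
3.605471e+03,6.592819e-19
3.992692e+03,7.979152e-21
4.421500e+03,6.011015e-23
4.896361e+03,2.678746e-25
5.422221e+03,6.674528e-28
6.004558e+03,8.735691e-31
6.649436e+03,5.604434e-34
7.363573e+03,1.632560e-37
8.154407e+03,1.983732e-41
9.030176e+03,9.153590e-46
1.000000e+04,1.445550e-50
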