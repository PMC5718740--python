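# element=I squared IT92 form factor vs x^2 (1/A^2)
x2_invA2,F2
0.000000e+00,2.809064e+03
1.000000e-03,2.761669e+03
1.107398e-03,2.756701e+03
1.226331e-03,2.751227e+03
1.358036e-03,2.745198e+03
1.503887e-03,2.738561e+03
1.665402e-03,2.731260e+03
1.844263e-03,2.723234e+03
2.042333e-03,2.714418e+03
2.261676e-03,2.704742e+03
2.504576e-03,2.694131e+03
2.773563e-03,2.682508e+03
3.071438e-03,2.669789e+03
3.401305e-03,2.655889e+03
3.766599e-03,2.640718e+03
4.171125e-03,2.624183e+03
4.619096e-03,2.606191e+03
5.115178e-03,2.586646e+03
5.664539e-03,2.565455e+03
6.272900e-03,2.542526e+03
6.946598e-03,2.517771e+03
7.692650e-03,2.491108e+03
8.518826e-03,2.462464e+03
9.433732e-03,2.431775e+03
1.044690e-02,2.398993e+03
1.156888e-02,2.364085e+03
1.281135e-02,2.327036e+03
1.418727e-02,2.287852e+03
1.571095e-02,2.246563e+03
1.739828e-02,2.203223e+03
1.926682e-02,2.157908e+03
2.133605e-02,2.110722e+03
2.362750e-02,2.061790e+03
2.616505e-02,2.011257e+03
2.897512e-02,1.959287e+03
3.208700e-02,1.906054e+03
3.553308e-02,1.851741e+03
3.934927e-02,1.796533e+03
4.357531e-02,1.740607e+03
4.825522e-02,1.684136e+03
5.343774e-02,1.627274e+03
5.917686e-02,1.570158e+03
6.553234e-02,1.512903e+03
7.257040e-02,1.455598e+03
8.036432e-02,1.398311e+03
8.899530e-02,1.341081e+03
9.855324e-02,1.283931e+03
1.091377e-01,1.226865e+03
1.208589e-01,1.169881e+03
1.338389e-01,1.112984e+03
1.482129e-01,1.056198e+03
1.641307e-01,9.995832e+02
1.817581e-01,9.432491e+02
2.012785e-01,8.873662e+02
2.228955e-01,8.321678e+02
2.468340e-01,7.779446e+02
2.733436e-01,7.250303e+02
3.027002e-01,6.737790e+02
3.352096e-01,6.245386e+02
3.712105e-01,5.776235e+02
4.110778e-01,5.332888e+02
4.552268e-01,4.917105e+02
5.041174e-01,4.529716e+02
5.582586e-01,4.170571e+02
6.182146e-01,3.838559e+02
6.846097e-01,3.531715e+02
7.581355e-01,3.247387e+02
8.395579e-01,2.982471e+02
9.297248e-01,2.733685e+02
1.029576e+00,2.497858e+02
1.140150e+00,2.272221e+02
1.262600e+00,2.054641e+02
1.398201e+00,1.843794e+02
1.548365e+00,1.639227e+02
1.714657e+00,1.441325e+02
1.898808e+00,1.251177e+02
2.102736e+00,1.070374e+02
2.328566e+00,9.007730e+01
2.578650e+00,7.442538e+01
2.855592e+00,6.025004e+01
3.162278e+00,4.768176e+01
3.501900e+00,3.679934e+01
3.877998e+00,2.762142e+01
4.294488e+00,2.010347e+01
4.755708e+00,1.414094e+01
5.266462e+00,9.578016e+00
5.832071e+00,6.221583e+00
6.458424e+00,3.858359e+00
7.152047e+00,2.273104e+00
7.920164e+00,1.265196e+00
8.770775e+00,6.612527e-01
9.712740e+00,3.223394e-01
1.075587e+01,1.454606e-01
1.191103e+01,6.026482e-02
1.319025e+01,2.271345e-02
1.460686e+01,7.708842e-03
1.617561e+01,2.329667e-03
1.791284e+01,6.191334e-04
1.983665e+01,1.427138e-04
2.196707e+01,2.809964e-05
2.432629e+01,4.646627e-06
2.693889e+01,6.333392e-07
2.983208e+01,6.969181e-08
3.303599e+01,6.050493e-09
3.658400e+01,4.040251e-10
4.051305e+01,2.017400e-11
4.486408e+01,7.301038e-13
4.968240e+01,1.850004e-14
5.501819e+01,3.158860e-16
6.092705e+01,3.483747e-18
6.747050e+01,2.367733e-20
7.471671e+01,9.414784e-23
8.274114e+01,2.067647e-25
9.162739e+01,2.353109e-28
1.014680e+02,1.293140e-31
1.123655e+02,3.173446e-35
1.244333e+02,3.189314e-39
1.377972e+02,1.192623e-43
1.525964e+02,1.492234e-48
1.689850e+02,5.554349e-54
1.871337e+02,5.399369e-60
2.072315e+02,1.186708e-66
2.294877e+02,5.026757e-74
2.541343e+02,3.438581e-82
2.814279e+02,3.123018e-91
3.116527e+02,3.031771e-101
3.451236e+02,2.474308e-112
3.821893e+02,1.301231e-124
4.232357e+02,3.284748e-138
4.686904e+02,2.872537e-153
5.190269e+02,6.064600e-170
5.747694e+02,2.072167e-188
6.364986e+02,7.358550e-209
7.048574e+02,1.663056e-231
7.805578e+02,1.389617e-256
8.643883e+02,2.352617e-284
9.572220e+02,4.145872e-315
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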