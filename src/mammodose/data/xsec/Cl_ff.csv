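# element=Cl squared IT92 form factor vs x^2 (1/A^2)
x2_invA2,F2
0.000000e+00,2.890170e+02
1.000000e-03,2.822581e+02
1.107398e-03,2.815484e+02
1.226331e-03,2.807662e+02
1.358036e-03,2.799043e+02
1.503887e-03,2.789552e+02
1.665402e-03,2.779107e+02
1.844263e-03,2.767619e+02
2.042333e-03,2.754993e+02
2.261676e-03,2.741129e+02
2.504576e-03,2.725917e+02
2.773563e-03,2.709242e+02
3.071438e-03,2.690985e+02
3.401305e-03,2.671017e+02
3.766599e-03,2.649207e+02
4.171125e-03,2.625418e+02
4.619096e-03,2.599513e+02
5.115178e-03,2.571349e+02
5.664539e-03,2.540788e+02
6.272900e-03,2.507695e+02
6.946598e-03,2.471938e+02
7.692650e-03,2.433399e+02
8.518826e-03,2.391971e+02
9.433732e-03,2.347568e+02
1.044690e-02,2.300125e+02
1.156888e-02,2.249609e+02
1.281135e-02,2.196018e+02
1.418727e-02,2.139393e+02
1.571095e-02,2.079818e+02
1.739828e-02,2.017427e+02
1.926682e-02,1.952410e+02
2.133605e-02,1.885009e+02
2.362750e-02,1.815524e+02
2.616505e-02,1.744312e+02
2.897512e-02,1.671778e+02
3.208700e-02,1.598373e+02
3.553308e-02,1.524582e+02
3.934927e-02,1.450916e+02
4.357531e-02,1.377898e+02
4.825522e-02,1.306045e+02
5.343774e-02,1.235859e+02
5.917686e-02,1.167809e+02
6.553234e-02,1.102320e+02
7.257040e-02,1.039758e+02
8.036432e-02,9.804204e+01
8.899530e-02,9.245306e+01
9.855324e-02,8.722272e+01
1.091377e-01,8.235605e+01
1.208589e-01,7.784879e+01
1.338389e-01,7.368724e+01
1.482129e-01,6.984837e+01
1.641307e-01,6.630037e+01
1.817581e-01,6.300381e+01
2.012785e-01,5.991350e+01
2.228955e-01,5.698103e+01
2.468340e-01,5.415784e+01
2.733436e-01,5.139864e+01
3.027002e-01,4.866456e+01
3.352096e-01,4.592580e+01
3.712105e-01,4.316326e+01
4.110778e-01,4.036902e+01
4.552268e-01,3.754581e+01
5.041174e-01,3.470554e+01
5.582586e-01,3.186745e+01
6.182146e-01,2.905606e+01
6.846097e-01,2.629919e+01
7.581355e-01,2.362619e+01
8.395579e-01,2.106625e+01
9.297248e-01,1.864686e+01
1.029576e+00,1.639237e+01
1.140150e+00,1.432268e+01
1.262600e+00,1.245223e+01
1.398201e+00,1.078922e+01
1.548365e+00,9.335426e+00
1.714657e+00,8.086346e+00
1.898808e+00,7.031942e+00
2.102736e+00,6.157682e+00
2.328566e+00,5.445840e+00
2.578650e+00,4.876824e+00
2.855592e+00,4.430383e+00
3.162278e+00,4.086577e+00
3.501900e+00,3.826473e+00
3.877998e+00,3.632612e+00
4.294488e+00,3.489306e+00
4.755708e+00,3.382853e+00
5.266462e+00,3.301685e+00
5.832071e+00,3.236442e+00
6.458424e+00,3.179923e+00
7.152047e+00,3.126905e+00
7.920164e+00,3.073828e+00
8.770775e+00,3.018410e+00
9.712740e+00,2.959259e+00
1.075587e+01,2.895539e+00
1.191103e+01,2.826733e+00
1.319025e+01,2.752495e+00
1.460686e+01,2.672571e+00
1.617561e+01,2.586771e+00
1.791284e+01,2.494968e+00
1.983665e+01,2.397103e+00
2.196707e+01,2.293200e+00
2.432629e+01,2.183385e+00
2.693889e+01,2.067901e+00
2.983208e+01,1.947129e+00
3.303599e+01,1.821599e+00
3.658400e+01,1.692008e+00
4.051305e+01,1.559229e+00
4.486408e+01,1.424314e+00
4.968240e+01,1.288488e+00
5.501819e+01,1.153135e+00
6.092705e+01,1.019774e+00
6.747050e+01,8.900094e-01
7.471671e+01,7.654860e-01
8.274114e+01,6.478134e-01
9.162739e+01,5.384899e-01
1.014680e+02,4.388177e-01
1.123655e+02,3.498192e-01
1.244333e+02,2.721641e-01
1.377972e+02,2.061153e-01
1.525964e+02,1.515042e-01
1.689850e+02,1.077411e-01
1.871337e+02,7.386495e-02
2.072315e+02,4.862822e-02
2.294877e+02,3.060837e-02
2.541343e+02,1.833157e-02
2.814279e+02,1.039078e-02
3.116527e+02,5.541374e-03
3.451236e+02,2.762254e-03
3.821893e+02,1.277726e-03
4.232357e+02,5.440665e-04
4.686904e+02,2.113706e-04
5.190269e+02,7.418886e-05
5.747694e+02,2.327010e-05
6.364986e+02,6.444341e-06
7.048574e+02,1.554789e-06
7.805578e+02,3.219921e-07
8.643883e+02,5.630893e-08
9.572220e+02,8.165452e-09
1.060026e+03,9.623196e-10
1.173871e+03,9.014092e-11
1.299942e+03,6.547518e-12
1.439554e+03,3.588571e-13
1.594159e+03,1.439861e-14
1.765369e+03,4.090037e-16
1.954966e+03,7.925608e-18
2.164926e+03,1.005536e-19
2.397435e+03,7.981193e-22
2.654915e+03,3.768481e-24
2.940048e+03,1.001076e-26
3.255804e+03,1.406510e-29
3.605471e+03,9.760769e-33
3.992692e+03,3.101638e-36
4.421500e+03,4.149836e-40
4.896361e+03,2.130382e-44
5.422221e+03,3.786097e-49
6.004558e+03,2.078530e-54
6.649436e+03,3.107132e-60
7.363573e+03,1.099832e-66
8.154407e+03,7.897026e-74
9.030176e+03,9.690881e-82
1.000000e+04,1.681223e-90
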