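# element=C Z=6 A=12.011
energy_MeV,photoelectric,incoherent,coherent
5.000000e-02,1.100000e-02,1.689189e-01,1.166115e-02
5.329071e-02,8.913408e-03,1.673039e-01,1.034789e-02
5.679799e-02,7.222621e-03,1.656288e-01,9.175165e-03
6.053610e-02,5.852561e-03,1.638938e-01,8.129313e-03
6.452024e-02,4.742387e-03,1.620992e-01,7.197774e-03
6.876658e-02,3.842803e-03,1.602457e-01,6.369034e-03
7.329240e-02,3.113861e-03,1.583341e-01,5.632558e-03
7.811608e-02,2.523192e-03,1.563658e-01,4.978735e-03
8.325722e-02,2.044567e-03,1.543422e-01,4.398827e-03
8.873673e-02,1.656733e-03,1.522651e-01,3.884907e-03
9.457686e-02,1.342467e-03,1.501365e-01,3.429813e-03
1.008014e-01,1.087814e-03,1.479589e-01,3.027086e-03
1.074355e-01,8.814663e-04,1.457347e-01,2.670922e-03
1.145063e-01,7.142608e-04,1.434668e-01,2.356111e-03
1.220424e-01,5.787725e-04,1.411583e-01,2.077994e-03
1.300746e-01,4.689850e-04,1.388126e-01,1.832407e-03
1.386353e-01,3.800231e-04,1.364331e-01,1.615635e-03
1.477595e-01,3.079365e-04,1.340234e-01,1.424374e-03
1.574841e-01,2.495239e-04,1.315872e-01,1.255683e-03
1.678488e-01,2.021917e-04,1.291284e-01,1.106951e-03
1.788957e-01,1.638379e-04,1.266508e-01,9.758635e-04
1.906695e-01,1.327595e-04,1.241583e-01,8.603682e-04
2.032183e-01,1.075763e-04,1.216548e-01,7.586486e-04
2.165929e-01,8.717012e-05,1.191440e-01,6.690977e-04
2.308478e-01,7.063480e-05,1.166296e-01,5.902952e-04
2.460409e-01,5.723607e-05,1.141152e-01,5.209862e-04
2.622338e-01,4.637895e-05,1.116042e-01,4.600626e-04
2.794925e-01,3.758132e-05,1.090997e-01,4.065464e-04
2.978871e-01,3.045251e-05,1.066048e-01,3.595742e-04
3.174923e-01,2.467597e-05,1.041223e-01,3.183839e-04
3.383878e-01,1.999518e-05,1.016548e-01,2.823019e-04
3.606585e-01,1.620229e-05,9.920465e-02,2.507328e-04
3.843949e-01,1.312887e-05,9.677395e-02,2.231493e-04
4.096936e-01,1.063845e-05,9.436462e-02,1.990833e-04
4.366572e-01,8.620443e-06,9.197837e-02,1.781190e-04
4.653954e-01,6.985229e-06,8.961669e-02,1.598863e-04
4.960251e-01,5.660200e-06,8.728089e-02,1.440552e-04
5.286705e-01,4.586515e-06,8.497211e-02,1.303313e-04
5.634645e-01,3.716498e-06,8.269135e-02,1.184526e-04
6.005485e-01,3.011515e-06,8.043947e-02,1.081852e-04
6.400731e-01,2.440260e-06,7.821720e-02,9.932165e-05
6.821990e-01,1.977367e-06,7.602522e-02,9.167728e-05
7.270973e-01,1.602279e-06,7.386409e-02,8.508869e-05
7.749506e-01,1.298343e-06,7.173433e-02,7.941146e-05
8.259534e-01,1.052060e-06,6.963641e-02,7.451862e-05
8.803128e-01,8.524944e-07,6.757077e-02,7.029917e-05
9.382499e-01,6.907845e-07,6.553781e-02,6.665689e-05
1.000000e+00,5.597495e-07,6.353794e-02,6.350909e-05
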