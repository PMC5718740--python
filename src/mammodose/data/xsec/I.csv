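# element=I Z=53 A=126.904
energy_MeV,photoelectric,incoherent,coherent
5.000000e-02,1.198000e+01,1.412234e-01,2.523541e-01
5.329071e-02,1.007504e+01,1.398732e-01,2.247272e-01
5.679799e-02,8.472989e+00,1.384728e-01,1.999245e-01
6.053610e-02,7.122969e+00,1.370222e-01,1.776857e-01
6.452024e-02,5.973997e+00,1.355218e-01,1.577739e-01
6.876658e-02,5.010360e+00,1.339722e-01,1.399715e-01
7.329240e-02,4.202163e+00,1.323741e-01,1.240779e-01
7.811608e-02,3.524333e+00,1.307285e-01,1.099077e-01
8.325722e-02,2.951190e+00,1.290367e-01,9.729042e-02
8.873673e-02,2.468932e+00,1.273001e-01,8.606925e-02
9.457686e-02,2.065481e+00,1.255206e-01,7.610064e-02
1.008014e-01,1.724434e+00,1.236999e-01,6.725361e-02
1.074355e-01,1.419314e+00,1.218404e-01,5.940906e-02
1.145063e-01,1.168181e+00,1.199444e-01,5.245904e-02
1.220424e-01,9.614840e-01,1.180144e-01,4.630606e-02
1.300746e-01,7.913596e-01,1.160533e-01,4.086228e-02
1.386353e-01,6.513369e-01,1.140639e-01,3.604878e-02
1.477595e-01,5.360898e-01,1.120493e-01,3.179482e-02
1.574841e-01,4.410211e-01,1.100125e-01,2.803712e-02
1.678488e-01,3.627574e-01,1.079568e-01,2.471920e-02
1.788957e-01,2.983824e-01,1.058855e-01,2.179069e-02
1.906695e-01,2.454314e-01,1.038017e-01,1.920679e-02
2.032183e-01,2.023097e-01,1.017086e-01,1.692765e-02
2.165929e-01,1.678361e-01,9.960949e-02,1.491792e-02
2.308478e-01,1.392368e-01,9.750737e-02,1.314623e-02
2.460409e-01,1.155109e-01,9.540521e-02,1.158478e-02
2.622338e-01,9.582781e-02,9.330586e-02,1.020898e-02
2.794925e-01,7.949875e-02,9.121201e-02,8.997054e-03
2.978871e-01,6.595216e-02,8.912618e-02,7.929748e-03
3.174923e-01,5.387369e-02,8.705072e-02,6.990053e-03
3.383878e-01,4.392241e-02,8.498777e-02,6.162937e-03
3.606585e-01,3.580928e-02,8.293933e-02,5.435126e-03
3.843949e-01,2.919477e-02,8.090716e-02,4.794897e-03
4.096936e-01,2.368323e-02,7.889286e-02,4.231900e-03
4.366572e-01,1.905306e-02,7.689785e-02,3.736997e-03
4.653954e-01,1.532810e-02,7.492338e-02,3.302124e-03
4.960251e-01,1.233139e-02,7.297055e-02,2.920161e-03
5.286705e-01,9.976356e-03,7.104032e-02,2.584823e-03
5.634645e-01,8.077568e-03,6.913350e-02,2.290563e-03
6.005485e-01,6.538288e-03,6.725083e-02,2.032485e-03
6.400731e-01,5.188389e-03,6.539293e-02,1.806269e-03
6.821990e-01,4.117190e-03,6.356033e-02,1.608101e-03
7.270973e-01,3.267152e-03,6.175354e-02,1.434621e-03
7.749506e-01,2.592614e-03,5.997297e-02,1.282874e-03
8.259534e-01,2.069149e-03,5.821901e-02,1.150265e-03
8.803128e-01,1.660820e-03,5.649205e-02,1.034522e-03
9.382499e-01,1.333070e-03,5.479241e-02,9.336555e-04
1.000000e+00,1.070000e-03,5.312043e-02,8.459205e-04
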