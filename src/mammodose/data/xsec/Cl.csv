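# element=Cl Z=17 A=35.45
energy_MeV,photoelectric,incoherent,coherent
5.000000e-02,4.340000e-01,1.621581e-01,8.689348e-02
5.329071e-02,3.516744e-01,1.606078e-01,8.025465e-02
5.679799e-02,2.849652e-01,1.589998e-01,7.418068e-02
6.053610e-02,2.309101e-01,1.573342e-01,6.860559e-02
6.452024e-02,1.871087e-01,1.556114e-01,6.346935e-02
6.876658e-02,1.516160e-01,1.538321e-01,5.871786e-02
7.329240e-02,1.228560e-01,1.519970e-01,5.430310e-02
7.811608e-02,9.955139e-02,1.501075e-01,5.018321e-02
8.325722e-02,8.066747e-02,1.481649e-01,4.632258e-02
8.873673e-02,6.536564e-02,1.461709e-01,4.269184e-02
9.457686e-02,5.296642e-02,1.441276e-01,3.926784e-02
1.008014e-01,4.291921e-02,1.420370e-01,3.603337e-02
1.074355e-01,3.477785e-02,1.399018e-01,3.297681e-02
1.145063e-01,2.818083e-02,1.377247e-01,3.009145e-02
1.220424e-01,2.283521e-02,1.355087e-01,2.737465e-02
1.300746e-01,1.850359e-02,1.332569e-01,2.482669e-02
1.386353e-01,1.499364e-02,1.309726e-01,2.244945e-02
1.477595e-01,1.214949e-02,1.286593e-01,2.024501e-02
1.574841e-01,9.844854e-03,1.263206e-01,1.821432e-02
1.678488e-01,7.977381e-03,1.239602e-01,1.635608e-02
1.788957e-01,6.464150e-03,1.215818e-01,1.466609e-02
1.906695e-01,5.237964e-03,1.191891e-01,1.313707e-02
2.032183e-01,4.244374e-03,1.167858e-01,1.175901e-02
2.165929e-01,3.439258e-03,1.143755e-01,1.052002e-02
2.308478e-01,2.786864e-03,1.119617e-01,9.407316e-03
2.460409e-01,2.258223e-03,1.095479e-01,8.408193e-03
2.622338e-01,1.829860e-03,1.071374e-01,7.510810e-03
2.794925e-01,1.482754e-03,1.047331e-01,6.704580e-03
2.978871e-01,1.201490e-03,1.023381e-01,5.980265e-03
3.174923e-01,9.735790e-04,9.995499e-02,5.329854e-03
3.383878e-01,7.889006e-04,9.758624e-02,4.746332e-03
3.606585e-01,6.392539e-04,9.523413e-02,4.223466e-03
3.843949e-01,5.179937e-04,9.290072e-02,3.755626e-03
4.096936e-01,4.197354e-04,9.058782e-02,3.337672e-03
4.366572e-01,3.401157e-04,8.829707e-02,2.964874e-03
4.653954e-01,2.755991e-04,8.602991e-02,2.632872e-03
4.960251e-01,2.233206e-04,8.378760e-02,2.337646e-03
5.286705e-01,1.809589e-04,8.157123e-02,2.075495e-03
5.634645e-01,1.466327e-04,7.938175e-02,1.843023e-03
6.005485e-01,1.188180e-04,7.722000e-02,1.637123e-03
6.400731e-01,9.627935e-05,7.508668e-02,1.454961e-03
6.821990e-01,7.801610e-05,7.298242e-02,1.293963e-03
7.270973e-01,6.321721e-05,7.090779e-02,1.151794e-03
7.749506e-01,5.122552e-05,6.886327e-02,1.026348e-03
8.259534e-01,4.150854e-05,6.684932e-02,9.157246e-04
8.803128e-01,3.363478e-05,6.486635e-02,8.182189e-04
9.382499e-01,2.725459e-05,6.291476e-02,7.323064e-04
1.000000e+00,2.208466e-05,6.099493e-02,6.566310e-04
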