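# element=N Z=7 A=14.007
energy_MeV,photoelectric,incoherent,coherent
5.000000e-02,1.900000e-02,1.689892e-01,2.690767e-02
5.329071e-02,1.539589e-02,1.673736e-01,2.512955e-02
5.679799e-02,1.247544e-02,1.656978e-01,2.350700e-02
6.053610e-02,1.010897e-02,1.639620e-01,2.202114e-02
6.452024e-02,8.191396e-03,1.621667e-01,2.065495e-02
6.876658e-02,6.637569e-03,1.603124e-01,1.939302e-02
7.329240e-02,5.378487e-03,1.584001e-01,1.822136e-02
7.811608e-02,4.358241e-03,1.564310e-01,1.712729e-02
8.325722e-02,3.531525e-03,1.544065e-01,1.609938e-02
8.873673e-02,2.861629e-03,1.523285e-01,1.512747e-02
9.457686e-02,2.318806e-03,1.501991e-01,1.420268e-02
1.008014e-01,1.878951e-03,1.480205e-01,1.331745e-02
1.074355e-01,1.522533e-03,1.457953e-01,1.246561e-02
1.145063e-01,1.233723e-03,1.435265e-01,1.164241e-02
1.220424e-01,9.996979e-04,1.412171e-01,1.084456e-02
1.300746e-01,8.100650e-04,1.388704e-01,1.007022e-02
1.386353e-01,6.564036e-04,1.364899e-01,9.318961e-03
1.477595e-01,5.318903e-04,1.340792e-01,8.591660e-03
1.574841e-01,4.309959e-04,1.316420e-01,7.890289e-03
1.678488e-01,3.492402e-04,1.291822e-01,7.217651e-03
1.788957e-01,2.829927e-04,1.267035e-01,6.577030e-03
1.906695e-01,2.293118e-04,1.242100e-01,5.971778e-03
2.032183e-01,1.858136e-04,1.217055e-01,5.404892e-03
2.165929e-01,1.505666e-04,1.191936e-01,4.878621e-03
2.308478e-01,1.220056e-04,1.166782e-01,4.394167e-03
2.460409e-01,9.886231e-05,1.141628e-01,3.951535e-03
2.622338e-01,8.010909e-05,1.116507e-01,3.549555e-03
2.794925e-01,6.491318e-05,1.091451e-01,3.186062e-03
2.978871e-01,5.259979e-05,1.066492e-01,2.858211e-03
3.174923e-01,4.262212e-05,1.041657e-01,2.562829e-03
3.383878e-01,3.453712e-05,1.016972e-01,2.296732e-03
3.606585e-01,2.798577e-05,9.924597e-02,2.056958e-03
3.843949e-01,2.267714e-05,9.681425e-02,1.840879e-03
4.096936e-01,1.837551e-05,9.440392e-02,1.646216e-03
4.366572e-01,1.488986e-05,9.201668e-02,1.470997e-03
4.653954e-01,1.206540e-05,8.965401e-02,1.313486e-03
4.960251e-01,9.776709e-06,8.731724e-02,1.172126e-03
5.286705e-01,7.922163e-06,8.500750e-02,1.045488e-03
5.634645e-01,6.419406e-06,8.272579e-02,9.322490e-04
6.005485e-01,5.201708e-06,8.047297e-02,8.311757e-04
6.400731e-01,4.214995e-06,7.824978e-02,7.411160e-04
6.821990e-01,3.415451e-06,7.605688e-02,6.609979e-04
7.270973e-01,2.767574e-06,7.389485e-02,5.898274e-04
7.749506e-01,2.242592e-06,7.176420e-02,5.266884e-04
8.259534e-01,1.817194e-06,6.966541e-02,4.707404e-04
8.803128e-01,1.472490e-06,6.759891e-02,4.212160e-04
9.382499e-01,1.193173e-06,6.556510e-02,3.774178e-04
1.000000e+00,9.668400e-07,6.356440e-02,3.387142e-04
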