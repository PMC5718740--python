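# element=Na Z=11 A=22.99
energy_MeV,photoelectric,incoherent,coherent
5.000000e-02,9.000000e-02,1.617930e-01,2.887753e-02
5.329071e-02,7.292788e-02,1.602462e-01,2.559416e-02
5.679799e-02,5.909418e-02,1.586418e-01,2.267180e-02
6.053610e-02,4.788459e-02,1.569799e-01,2.007231e-02
6.452024e-02,3.880135e-02,1.552610e-01,1.776160e-02
6.876658e-02,3.144111e-02,1.534857e-01,1.570911e-02
7.329240e-02,2.547704e-02,1.516548e-01,1.388736e-02
7.811608e-02,2.064430e-02,1.497695e-01,1.227161e-02
8.325722e-02,1.672828e-02,1.478313e-01,1.083959e-02
8.873673e-02,1.355509e-02,1.458418e-01,9.571262e-03
9.457686e-02,1.098382e-02,1.438030e-01,8.448630e-03
1.008014e-01,8.900296e-03,1.417172e-01,7.455534e-03
1.074355e-01,7.211997e-03,1.395868e-01,6.577501e-03
1.145063e-01,5.843952e-03,1.374146e-01,5.801580e-03
1.220424e-01,4.735411e-03,1.352036e-01,5.116204e-03
1.300746e-01,3.837150e-03,1.329568e-01,4.511056e-03
1.386353e-01,3.109280e-03,1.306777e-01,3.976946e-03
1.477595e-01,2.519480e-03,1.283696e-01,3.505699e-03
1.574841e-01,2.041560e-03,1.260362e-01,3.090051e-03
1.678488e-01,1.654296e-03,1.236811e-01,2.723552e-03
1.788957e-01,1.340492e-03,1.213080e-01,2.400484e-03
1.906695e-01,1.086214e-03,1.189207e-01,2.115780e-03
2.032183e-01,8.801696e-04,1.165228e-01,1.864951e-03
2.165929e-01,7.132101e-04,1.141179e-01,1.644027e-03
2.308478e-01,5.779211e-04,1.117096e-01,1.449492e-03
2.460409e-01,4.682951e-04,1.093013e-01,1.278241e-03
2.622338e-01,3.794641e-04,1.068962e-01,1.127524e-03
2.794925e-01,3.074835e-04,1.044973e-01,9.949148e-04
2.978871e-01,2.491569e-04,1.021077e-01,8.782651e-04
3.174923e-01,2.018943e-04,9.972993e-02,7.756790e-04
3.383878e-01,1.635969e-04,9.736651e-02,6.854828e-04
3.606585e-01,1.325642e-04,9.501970e-02,6.062006e-04
3.843949e-01,1.074180e-04,9.269154e-02,5.365336e-04
4.096936e-01,8.704189e-05,9.038385e-02,4.753405e-04
4.366572e-01,7.053090e-05,8.809826e-02,4.216198e-04
4.653954e-01,5.715188e-05,8.583621e-02,3.744936e-04
4.960251e-01,4.631073e-05,8.359894e-02,3.331923e-04
5.286705e-01,3.752603e-05,8.138756e-02,2.970412e-04
5.634645e-01,3.040771e-05,7.920302e-02,2.654478e-04
6.005485e-01,2.463967e-05,7.704613e-02,2.378912e-04
6.400731e-01,1.996576e-05,7.491761e-02,2.139132e-04
6.821990e-01,1.617845e-05,7.281810e-02,1.931089e-04
7.270973e-01,1.310956e-05,7.074813e-02,1.751200e-04
7.749506e-01,1.062280e-05,6.870822e-02,1.596273e-04
8.259534e-01,8.607762e-06,6.669880e-02,1.463447e-04
8.803128e-01,6.974954e-06,6.472029e-02,1.350141e-04
9.382499e-01,5.651874e-06,6.277310e-02,1.254009e-04
1.000000e+00,4.579768e-06,6.085759e-02,1.172909e-04
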