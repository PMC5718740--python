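# element=H Z=1 A=1.008
energy_MeV,photoelectric,incoherent,coherent
5.000000e-02,1.000000e-05,3.354637e-01,1.461013e-03
5.329071e-02,8.103098e-06,3.322564e-01,1.287203e-03
5.679799e-02,6.566020e-06,3.289298e-01,1.133967e-03
6.053610e-02,5.320510e-06,3.254842e-01,9.988937e-04
6.452024e-02,4.311261e-06,3.219202e-01,8.798497e-04
6.876658e-02,3.493457e-06,3.182392e-01,7.749484e-04
7.329240e-02,2.830783e-06,3.144430e-01,6.825218e-04
7.811608e-02,2.293811e-06,3.105341e-01,6.010962e-04
8.325722e-02,1.858697e-06,3.065153e-01,5.293702e-04
8.873673e-02,1.506121e-06,3.023903e-01,4.661951e-04
9.457686e-02,1.220424e-06,2.981630e-01,4.105569e-04
1.008014e-01,9.889218e-07,2.938383e-01,3.615613e-04
1.074355e-01,8.013330e-07,2.894211e-01,3.184197e-04
1.145063e-01,6.493280e-07,2.849173e-01,2.804366e-04
1.220424e-01,5.261568e-07,2.803328e-01,2.469991e-04
1.300746e-01,4.263500e-07,2.756743e-01,2.175671e-04
1.386353e-01,3.454756e-07,2.709487e-01,1.916647e-04
1.477595e-01,2.799423e-07,2.661631e-01,1.688728e-04
1.574841e-01,2.268399e-07,2.613250e-01,1.488223e-04
1.678488e-01,1.838106e-07,2.564420e-01,1.311883e-04
1.788957e-01,1.489436e-07,2.515216e-01,1.156850e-04
1.906695e-01,1.206904e-07,2.465717e-01,1.020608e-04
2.032183e-01,9.779663e-08,2.415999e-01,9.009444e-05
2.165929e-01,7.924556e-08,2.366136e-01,7.959148e-05
2.308478e-01,6.421346e-08,2.316201e-01,7.038103e-05
2.460409e-01,5.203279e-08,2.266267e-01,6.231298e-05
2.622338e-01,4.216268e-08,2.216398e-01,5.525550e-05
2.794925e-01,3.416483e-08,2.166661e-01,4.909283e-05
2.978871e-01,2.768410e-08,2.117114e-01,4.372332e-05
3.174923e-01,2.243270e-08,2.067813e-01,3.905762e-05
3.383878e-01,1.817743e-08,2.018810e-01,3.501706e-05
3.606585e-01,1.472935e-08,1.970151e-01,3.153219e-05
3.843949e-01,1.193534e-08,1.921878e-01,2.854146e-05
4.096936e-01,9.671321e-09,1.874030e-01,2.598997e-05
4.366572e-01,7.836766e-09,1.826641e-01,2.382841e-05
4.653954e-01,6.350209e-09,1.779739e-01,2.201211e-05
4.960251e-01,5.145636e-09,1.733351e-01,2.050025e-05
5.286705e-01,4.169559e-09,1.687500e-01,1.925519e-05
5.634645e-01,3.378635e-09,1.642205e-01,1.824207e-05
6.005485e-01,2.737741e-09,1.597484e-01,1.742852e-05
6.400731e-01,2.218418e-09,1.553351e-01,1.678455e-05
6.821990e-01,1.797606e-09,1.509820e-01,1.628265e-05
7.270973e-01,1.456618e-09,1.466901e-01,1.589790e-05
7.749506e-01,1.180312e-09,1.424605e-01,1.560811e-05
8.259534e-01,9.564180e-10,1.382941e-01,1.539390e-05
8.803128e-01,7.749949e-10,1.341919e-01,1.523867e-05
9.382499e-01,6.279860e-10,1.301545e-01,1.512847e-05
1.000000e+00,5.088632e-10,1.261829e-01,1.505182e-05
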