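# mean Compton energy-transfer fraction (free-electron Klein-Nishina)
energy_MeV,transfer_fraction
5.000000e-02,8.070780e-02
5.329071e-02,8.505478e-02
5.679799e-02,8.958414e-02
6.053610e-02,9.429833e-02
6.452024e-02,9.919933e-02
6.876658e-02,1.042886e-01
7.329240e-02,1.095671e-01
7.811608e-02,1.150353e-01
8.325722e-02,1.206930e-01
8.873673e-02,1.265393e-01
9.457686e-02,1.325730e-01
1.008014e-01,1.387922e-01
1.074355e-01,1.451943e-01
1.145063e-01,1.517763e-01
1.220424e-01,1.585345e-01
1.300746e-01,1.654649e-01
1.386353e-01,1.725628e-01
1.477595e-01,1.798233e-01
1.574841e-01,1.872410e-01
1.678488e-01,1.948100e-01
1.788957e-01,2.025245e-01
1.906695e-01,2.103781e-01
2.032183e-01,2.183645e-01
2.165929e-01,2.264769e-01
2.308478e-01,2.347087e-01
2.460409e-01,2.430529e-01
2.622338e-01,2.515027e-01
2.794925e-01,2.600511e-01
2.978871e-01,2.686910e-01
3.174923e-01,2.774152e-01
3.383878e-01,2.862165e-01
3.606585e-01,2.950876e-01
3.843949e-01,3.040210e-01
4.096936e-01,3.130092e-01
4.366572e-01,3.220444e-01
4.653954e-01,3.311189e-01
4.960251e-01,3.402245e-01
5.286705e-01,3.493533e-01
5.634645e-01,3.584967e-01
6.005485e-01,3.676465e-01
6.400731e-01,3.767940e-01
6.821990e-01,3.859307e-01
7.270973e-01,3.950480e-01
7.749506e-01,4.041371e-01
8.259534e-01,4.131895e-01
8.803128e-01,4.221968e-01
9.382499e-01,4.311506e-01
1.000000e+00,4.400428e-01
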