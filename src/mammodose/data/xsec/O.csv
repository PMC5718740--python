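# element=O Z=8 A=15.999
energy_MeV,photoelectric,incoherent,coherent
5.000000e-02,3.000000e-02,1.690843e-01,1.895496e-02
5.329071e-02,2.430929e-02,1.674677e-01,1.684590e-02
5.679799e-02,1.969806e-02,1.657910e-01,1.496088e-02
6.053610e-02,1.596153e-02,1.640543e-01,1.327714e-02
6.452024e-02,1.293378e-02,1.622579e-01,1.177445e-02
6.876658e-02,1.048037e-02,1.604026e-01,1.043462e-02
7.329240e-02,8.492348e-03,1.584892e-01,9.241211e-03
7.811608e-02,6.881432e-03,1.565189e-01,8.179311e-03
8.325722e-02,5.576092e-03,1.544934e-01,7.235375e-03
8.873673e-02,4.518362e-03,1.524142e-01,6.397099e-03
9.457686e-02,3.661273e-03,1.502836e-01,5.653321e-03
1.008014e-01,2.966765e-03,1.481037e-01,4.993935e-03
1.074355e-01,2.403999e-03,1.458774e-01,4.409811e-03
1.145063e-01,1.947984e-03,1.436073e-01,3.892718e-03
1.220424e-01,1.578470e-03,1.412966e-01,3.435256e-03
1.300746e-01,1.279050e-03,1.389486e-01,3.030779e-03
1.386353e-01,1.036427e-03,1.365667e-01,2.673338e-03
1.477595e-01,8.398268e-04,1.341546e-01,2.357615e-03
1.574841e-01,6.805198e-04,1.317160e-01,2.078860e-03
1.678488e-01,5.514319e-04,1.292548e-01,1.832846e-03
1.788957e-01,4.468307e-04,1.267748e-01,1.615808e-03
1.906695e-01,3.620713e-04,1.242799e-01,1.424401e-03
2.032183e-01,2.933899e-04,1.217739e-01,1.255657e-03
2.165929e-01,2.377367e-04,1.192607e-01,1.106945e-03
2.308478e-01,1.926404e-04,1.167439e-01,9.759316e-04
2.460409e-01,1.560984e-04,1.142270e-01,8.605550e-04
2.622338e-01,1.264880e-04,1.117135e-01,7.589901e-04
2.794925e-01,1.024945e-04,1.092065e-01,6.696247e-04
2.978871e-01,8.305230e-05,1.067092e-01,5.910352e-04
3.174923e-01,6.729809e-05,1.042243e-01,5.219649e-04
3.383878e-01,5.453230e-05,1.017544e-01,4.613053e-04
3.606585e-01,4.418806e-05,9.930180e-02,4.080786e-04
3.843949e-01,3.580601e-05,9.686871e-02,3.614226e-04
4.096936e-01,2.901396e-05,9.445703e-02,3.205760e-04
4.366572e-01,2.351030e-05,9.206844e-02,2.848669e-04
4.653954e-01,1.905063e-05,8.970444e-02,2.537009e-04
4.960251e-01,1.543691e-05,8.736636e-02,2.265515e-04
5.286705e-01,1.250868e-05,8.505532e-02,2.029509e-04
5.634645e-01,1.013590e-05,8.277232e-02,1.824828e-04
6.005485e-01,8.213222e-06,8.051823e-02,1.647754e-04
6.400731e-01,6.655255e-06,7.829380e-02,1.494964e-04
6.821990e-01,5.392818e-06,7.609967e-02,1.363477e-04
7.270973e-01,4.369853e-06,7.393642e-02,1.250621e-04
7.749506e-01,3.540935e-06,7.180457e-02,1.154000e-04
8.259534e-01,2.869254e-06,6.970460e-02,1.071464e-04
8.803128e-01,2.324985e-06,6.763693e-02,1.001092e-04
9.382499e-01,1.883958e-06,6.560199e-02,9.411710e-05
1.000000e+00,1.526589e-06,6.360016e-02,8.901870e-05
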