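# Ir-192 photon line spectrum restricted to 0.060-0.885 MeV, 34 bins.
# Transcribed from the standard Ir-192 decay scheme (beta- branch to Pt-192,
# EC branch to Os-192): gamma lines plus Pt/Os K fluorescence x-rays above
# 60 keV.  Intensities are photons per 100 decays before normalization;
# lines below 60 keV (excluded here) are outside the transport cutoff.
energy_MeV,relative_intensity
0.061486,1.19
0.063000,2.05
0.065122,2.66
0.066831,4.53
0.071080,0.80
0.073363,0.29
0.075749,1.85
0.077850,0.55
0.110400,0.012
0.136343,0.199
0.176980,0.0043
0.201311,0.473
0.205794,3.34
0.280270,0.009
0.283267,0.266
0.295957,28.71
0.308455,29.70
0.316506,82.86
0.329170,0.0174
0.374485,0.727
0.416469,0.670
0.420520,0.069
0.468069,47.84
0.484575,3.189
0.485300,0.0023
0.489060,0.438
0.588581,4.522
0.593490,0.0421
0.599410,0.0039
0.604411,8.23
0.612462,5.34
0.624580,0.0104
0.703850,0.0053
0.884537,0.292
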