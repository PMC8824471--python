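# Optimized rate parameters, Scn4b-/- (Navbeta4-null) Purkinje-neuron Nav current model.
label = Scn4b-/-
q10 = 3.0
temperature_K = 295.0
a11_variable1 = 2.0761e-02
a11_variable2 = 9.7685e+02
a12 = 8.3340e+02
a13 = 6.1087e+01
b11_variable1 = 1.6995e-01
b11_variable2 = 1.8560e+01
b12 = 9.3042e+01
b13 = 1.7914e+02
a3_variable1 = 3.9273e-01
a3_variable2 = 9.8807e+02
b3_variable1 = 4.7402e+01
b3_variable2 = 1.3469e+01
a2_variable1 = 8.1085e+01
a2_variable2 = 9.9984e+02
a6_variable1 = 6.0756e+02
a6_variable2 = 7.8591e+01
b6_variable1 = 1.6214e+02
b6_variable2 = 4.3656e+01
a2s_variable1 = 2.3130e+01
a2s_variable2 = 9.9969e+02
b2s_variable1 = 1.0208e-03
b2s_variable2 = 1.1383e+01
a3s_variable1 = 2.8677e-03
a3s_variable2 = 9.8330e+02
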