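# Optimized rate parameters, wild-type Purkinje-neuron Nav current model.
label = WT
q10 = 3.0
temperature_K = 295.0
a11_variable1 = 2.3989e-02
a11_variable2 = 9.6108e+02
a12 = 8.5613e+02
a13 = 7.2682e+01
b11_variable1 = 1.7233e-01
b11_variable2 = 1.9691e+01
b12 = 8.8549e+01
b13 = 1.4841e+02
a3_variable1 = 3.6734e-01
a3_variable2 = 9.8034e+02
b3_variable1 = 5.3241e+01
b3_variable2 = 1.4204e+01
a2_variable1 = 8.7852e+01
a2_variable2 = 9.9972e+02
a6_variable1 = 6.0921e+02
a6_variable2 = 8.6490e+01
b6_variable1 = 1.5645e+02
b6_variable2 = 3.0317e+01
a2s_variable1 = 1.5817e+01
a2s_variable2 = 9.9982e+02
b2s_variable1 = 1.0010e-03
b2s_variable2 = 1.1963e+01
a3s_variable1 = 4.4773e-03
a3s_variable2 = 9.9993e+02
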