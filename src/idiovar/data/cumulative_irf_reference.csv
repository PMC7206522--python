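group,patient,lag0,lag1,lag2,lag3,lag4,lag5,lag6,lag7,lag8,lag9,lag10
tib_to_dep,3,0.06,0.29,0.51,0.53,0.53,0.53,0.52,0.52,0.52,0.52,0.52
tib_to_dep,6,0.02,0.25,0.31,0.32,0.32,0.31,0.31,0.31,0.31,0.31,0.31
tib_to_dep,20,0.44,0.89,1.00,1.02,1.03,1.03,1.03,1.03,1.03,1.03,1.03
dep_to_tib,10,0.00,7.46,9.17,9.35,9.34,9.33,9.33,9.33,9.33,9.33,9.33
dep_to_tib,11,0.00,8.42,9.44,9.72,9.78,9.79,9.79,9.79,9.79,9.79,9.79
dep_to_tib,14,0.00,12.74,13.33,13.55,13.57,13.57,13.57,13.57,13.57,13.57,13.57
dep_to_tib,19,0.00,-7.16,-20.71,-22.59,-23.64,-23.81,-23.66,-23.63,-23.60,-23.60,-23.60
tst_to_dep,6,0.06,0.27,0.32,0.32,0.32,0.32,0.32,0.32,0.32,0.32,0.32
tst_to_dep,7,0.09,-0.16,-0.13,-0.14,-0.14,-0.14,-0.14,-0.14,-0.14,-0.14,-0.14
tst_to_dep,14,0.08,-0.11,-0.10,-0.10,-0.10,-0.10,-0.10,-0.10,-0.10,-0.10,-0.10
tst_to_dep,19,-0.17,-0.46,-0.48,-0.49,-0.49,-0.49,-0.49,-0.49,-0.49,-0.49,-0.49
tst_to_dep,20,-0.24,0.20,0.23,0.23,0.23,0.23,0.23,0.23,0.23,0.23,0.23
tst_to_dep,21,0.36,0.09,-0.03,-0.10,-0.25,-0.40,-0.40,-0.35,-0.30,-0.27,-0.24
dep_to_tst,2,0.00,9.28,20.88,27.44,28.44,27.79,27.23,27.49,28.03,28.44,28.55
dep_to_tst,11,0.00,9.11,10.24,10.57,10.63,10.64,10.65,10.65,10.65,10.65,10.65
dep_to_tst,22,0.00,-9.46,-9.36,-9.37,-9.37,-9.37,-9.37,-9.37,-9.37,-9.37,-9.37
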