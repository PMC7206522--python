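group,patient,lag1,lag2,lag3,lag4,lag5,lag6,lag8,lag9,lag10
tib_to_dep,3,0.00,0.07,0.12,0.12,0.12,0.12,0.12,0.12,0.12
tib_to_dep,6,0.00,0.04,0.05,0.05,0.05,0.05,0.05,0.05,0.05
tib_to_dep,20,0.06,0.12,0.13,0.13,0.13,0.13,0.13,0.13,0.13
dep_to_tib,10,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03
dep_to_tib,11,0.02,0.02,0.02,0.02,0.02,0.02,0.02,0.02,0.02
dep_to_tib,14,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03
dep_to_tib,19,0.00,0.01,0.04,0.04,0.04,0.04,0.04,0.04,0.04
tst_to_dep,6,0.00,0.04,0.04,0.04,0.04,0.04,0.04,0.04,0.04
tst_to_dep,7,0.00,0.02,0.02,0.02,0.02,0.02,0.02,0.02,0.02
tst_to_dep,14,0.01,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03
tst_to_dep,19,0.01,0.04,0.04,0.04,0.04,0.04,0.04,0.04,0.04
tst_to_dep,20,0.02,0.08,0.08,0.08,0.08,0.08,0.08,0.08,0.08
tst_to_dep,21,0.09,0.13,0.14,0.14,0.15,0.16,0.16,0.16,0.16
dep_to_tst,2,0.00,0.02,0.04,0.05,0.05,0.05,0.05,0.05,0.05
dep_to_tst,11,0.00,0.02,0.02,0.02,0.02,0.02,0.02,0.02,0.02
dep_to_tst,22,0.00,0.03,0.03,0.03,0.03,0.03,0.03,0.03,0.03
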