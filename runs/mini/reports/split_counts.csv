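modality,n_train,n_test
glue,113,62
heterobifunctional,81,69
other,97,78
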