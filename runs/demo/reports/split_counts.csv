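modality,n_train,n_test
glue,416,284
heterobifunctional,348,252
other,373,327
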