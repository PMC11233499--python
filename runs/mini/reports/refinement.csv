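model,task_id,n,mae
original,CYP3A4_IC50,14,0.6538122429670425
original,CYP3A4_kobs,14,0.5423337497325261
original,HLM_CLint,21,0.7418969691419957
original,LE-MDCK_v2_Papp,21,1.0254778979950867
original,LogD,18,1.0282217917237984
original,RLM_CLint,19,0.4199014630995022
retrained,CYP3A4_IC50,14,0.9033249115507319
retrained,CYP3A4_kobs,14,0.5991696974183439
retrained,HLM_CLint,21,0.677670528943751
retrained,LE-MDCK_v2_Papp,21,1.2303501203625518
retrained,LogD,18,0.8414567702222256
retrained,RLM_CLint,19,0.4402720847814155
fine_tuned_modality_specific,CYP3A4_IC50,14,0.6454645853752682
fine_tuned_modality_specific,CYP3A4_kobs,14,0.531449397529838
fine_tuned_modality_specific,HLM_CLint,21,0.7194218872621017
fine_tuned_modality_specific,LE-MDCK_v2_Papp,21,0.9918270588588569
fine_tuned_modality_specific,LogD,18,1.0362443756756503
fine_tuned_modality_specific,RLM_CLint,19,0.41982155141326877
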