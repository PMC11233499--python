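task_id,pearson_r,spearman_rho,n,flag
CYP3A4_IC50,-0.004789060399223807,0.0480672268907563,50,
CYP3A4_kobs,-0.12513253644737962,-0.20701080432172866,50,
HLM_CLint,0.41192398972691185,0.34463385354141657,50,
LE-MDCK_v2_Papp,0.3917808704893937,0.3835294117647059,50,
LogD,-0.5291083005771963,-0.5479471788715485,50,
RLM_CLint,0.6837254698468226,0.64062424969988,50,
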