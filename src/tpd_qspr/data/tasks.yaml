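# Default prediction-task registry: 25 ADME/physicochemical assay endpoints
# grouped into four multi-task model families (permeability 5, clearance 6,
# binding/lipophilicity 10, CYP inhibition 4).
#
# Risk rules are expressed on the RAW assay scale. Units:
#   P_app          10^-6 cm/s        (apparent permeability)
#   CL_int         uL min^-1 mg^-1   (intrinsic clearance, microsomal protein)
#   F_u            fraction unbound  (0-1)
#   k_obs          min^-1            (CYP3A4 TDI inactivation rate)
#   IC_50          uM                (half-maximal inhibitory concentration)
#   LogP/LogD      unitless log10 partition/distribution coefficients
#   efflux_ratio   unitless
tasks:
  # ---- Permeability model (5 tasks) ----
  - task_id: LE-MDCK_v1_Papp
    model_group: permeability
    raw_quantity: P_app
    transform: log10
    evaluated: false
  - task_id: LE-MDCK_v2_Papp
    model_group: permeability
    raw_quantity: P_app
    transform: log10
    low_risk: {op: ">", threshold: 5.0}
    high_risk: {op: "<=", threshold: 1.5}
    evaluated: true
  - task_id: PAMPA_Papp
    model_group: permeability
    raw_quantity: P_app
    transform: log10
    evaluated: false
  - task_id: Caco2_Papp
    model_group: permeability
    raw_quantity: P_app
    transform: log10
    evaluated: false
  - task_id: MDCK-MDR1_efflux_ratio
    model_group: permeability
    raw_quantity: efflux_ratio
    transform: log10
    evaluated: false

  # ---- Clearance model (6 tasks) ----
  - task_id: RLM_CLint
    model_group: clearance
    raw_quantity: CL_int
    transform: log10
    low_risk: {op: "<=", threshold: 100.0}
    high_risk: {op: ">", threshold: 300.0}
    evaluated: true
  - task_id: HLM_CLint
    model_group: clearance
    raw_quantity: CL_int
    transform: log10
    low_risk: {op: "<=", threshold: 100.0}
    high_risk: {op: ">", threshold: 300.0}
    evaluated: true
  - task_id: MLM_CLint
    model_group: clearance
    raw_quantity: CL_int
    transform: log10
    evaluated: true
  - task_id: DLM_CLint
    model_group: clearance
    raw_quantity: CL_int
    transform: log10
    evaluated: true
  - task_id: CyLM_CLint
    model_group: clearance
    raw_quantity: CL_int
    transform: log10
    evaluated: true
  - task_id: MpLM_CLint
    model_group: clearance
    raw_quantity: CL_int
    transform: log10
    evaluated: false

  # ---- Binding / Lipophilicity model (10 tasks) ----
  - task_id: rPPB
    model_group: binding_lipophilicity
    raw_quantity: F_u
    transform: log10
    evaluated: true
  - task_id: hPPB
    model_group: binding_lipophilicity
    raw_quantity: F_u
    transform: log10
    evaluated: true
  - task_id: mPPB
    model_group: binding_lipophilicity
    raw_quantity: F_u
    transform: log10
    evaluated: false
  - task_id: dPPB
    model_group: binding_lipophilicity
    raw_quantity: F_u
    transform: log10
    evaluated: false
  - task_id: cynoPPB
    model_group: binding_lipophilicity
    raw_quantity: F_u
    transform: log10
    evaluated: true
  - task_id: HSA_binding
    model_group: binding_lipophilicity
    raw_quantity: F_u
    transform: log10
    evaluated: false
  - task_id: microsomal_binding
    model_group: binding_lipophilicity
    raw_quantity: F_u
    transform: log10
    evaluated: false
  - task_id: brain_binding
    model_group: binding_lipophilicity
    raw_quantity: F_u
    transform: log10
    evaluated: false
  - task_id: LogP
    model_group: binding_lipophilicity
    raw_quantity: LogP
    transform: identity
    evaluated: true
  - task_id: LogD
    model_group: binding_lipophilicity
    raw_quantity: LogD
    transform: identity
    evaluated: true

  # ---- CYP inhibition model (4 tasks) ----
  - task_id: CYP3A4_kobs
    model_group: cyp_inhibition
    raw_quantity: k_obs
    transform: log10
    low_risk: {op: "<", threshold: 0.01}
    high_risk: {op: ">", threshold: 0.025}
    evaluated: true
  - task_id: CYP3A4_IC50
    model_group: cyp_inhibition
    raw_quantity: IC_50
    transform: neg_log10_molar
    low_risk: {op: ">=", threshold: 10.0}
    high_risk: {op: "<", threshold: 1.0}
    evaluated: true
  - task_id: CYP2C9_IC50
    model_group: cyp_inhibition
    raw_quantity: IC_50
    transform: neg_log10_molar
    evaluated: true
  - task_id: CYP2D6_IC50
    model_group: cyp_inhibition
    raw_quantity: IC_50
    transform: neg_log10_molar
    evaluated: true
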