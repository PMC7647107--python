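# Default codebook for the household water treatment (HWT) behaviour survey.
#
# One entry per survey variable.  Roles:
#   id             household identifier
#   sec            socio-economic characteristic (categorical; `derived: true`
#                  marks nodes computed by the pipeline, not raw columns)
#   ranas_item     psychosocial sub-factor item (Likert 1-5 or binary 0/1),
#                  assigned to one of the five RANAS factors
#   asset          binary asset-checklist item feeding the wealth index
#   behaviour_item HWT behaviour item feeding the outcome score
# `polarity: reverse` marks items worded so that a high raw answer means less
# of the construct; they are flipped before scoring.
variables:
  - {name: household_id, role: id, scale: count}

  # --- socio-economic characteristics -------------------------------------
  - {name: water_health_problem, role: sec, scale: categorical,
     states: ["No", "Yes"]}
  - {name: information_access, role: sec, scale: categorical,
     states: ["Difficult", "Medium", "Easy"]}
  - {name: mother_education, role: sec, scale: categorical,
     states: ["None", "Primary", "Secondary", "Higher"]}
  - {name: father_education, role: sec, scale: categorical,
     states: ["None", "Primary", "Secondary", "Higher"]}
  - {name: wealth, role: sec, scale: categorical,
     states: ["Poor", "Middle", "Rich"], derived: true}
  - {name: religion, role: sec, scale: categorical,
     states: ["Christian", "Islam"]}
  - {name: accessibility, role: sec, scale: categorical,
     states: ["Difficult", "Easy"]}
  - {name: access_water, role: sec, scale: categorical,
     states: ["Far", "Medium", "Close"]}

  # --- RANAS psychosocial items --------------------------------------------
  - {name: perceived_vulnerability, role: ranas_item, factor: Risk,
     scale: likert_1_5}
  - {name: health_knowledge, role: ranas_item, factor: Risk, scale: likert_1_5}
  - {name: perceived_severity, role: ranas_item, factor: Risk,
     scale: likert_1_5}

  - {name: health_benefit, role: ranas_item, factor: Attitude,
     scale: likert_1_5}
  - {name: affective_taste, role: ranas_item, factor: Attitude,
     scale: likert_1_5}
  - {name: affective_enjoy, role: ranas_item, factor: Attitude,
     scale: likert_1_5}

  - {name: descriptive_norm, role: ranas_item, factor: Norm, scale: likert_1_5}
  - {name: injunctive_norm, role: ranas_item, factor: Norm, scale: likert_1_5}
  - {name: personal_norm, role: ranas_item, factor: Norm, scale: likert_1_5}

  - {name: confidence_performance, role: ranas_item, factor: Ability,
     scale: likert_1_5}
  - {name: confidence_recovering, role: ranas_item, factor: Ability,
     scale: likert_1_5}
  - {name: confidence_continuation, role: ranas_item, factor: Ability,
     scale: likert_1_5}

  - {name: action_control, role: ranas_item, factor: Self-regulation,
     scale: likert_1_5}
  - {name: remembering, role: ranas_item, factor: Self-regulation,
     scale: likert_1_5, polarity: reverse}
  - {name: commitment, role: ranas_item, factor: Self-regulation,
     scale: likert_1_5}
  - {name: barrier_planning, role: ranas_item, factor: Self-regulation,
     scale: binary_0_1}

  # --- asset checklist (wealth index) --------------------------------------
  - {name: asset_radio, role: asset, scale: binary_0_1}
  - {name: asset_tv, role: asset, scale: binary_0_1}
  - {name: asset_fridge, role: asset, scale: binary_0_1}
  - {name: asset_mobile_phone, role: asset, scale: binary_0_1}
  - {name: asset_motorcycle, role: asset, scale: binary_0_1}
  - {name: asset_bicycle, role: asset, scale: binary_0_1}
  - {name: asset_electricity, role: asset, scale: binary_0_1}
  - {name: asset_improved_floor, role: asset, scale: binary_0_1}
  - {name: asset_own_toilet, role: asset, scale: binary_0_1}
  - {name: asset_bank_account, role: asset, scale: binary_0_1}

  # --- HWT behaviour items --------------------------------------------------
  - {name: self_report_treat, role: behaviour_item, scale: binary_0_1}
  - {name: raw_water_frequency, role: behaviour_item, scale: likert_1_5,
     polarity: reverse}
  - {name: pct_water_treated, role: behaviour_item, scale: likert_1_5}
  - {name: hwt_habit, role: behaviour_item, scale: likert_1_5}
  - {name: hwt_intention, role: behaviour_item, scale: likert_1_5}
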