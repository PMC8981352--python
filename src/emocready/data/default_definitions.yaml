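# Default emergency-readiness definition set.
#
# Representative resource lists for the five measurable obstetric emergencies,
# assembled from WHO first-line emergency obstetric care guidance: the
# three-drug antibiotic escalation sequence (ampicillin, gentamicin,
# metronidazole), oxytocin as the uterotonic tracer, magnesium sulfate as the
# anticonvulsant tracer, and the standard proxy substitutions (electrical
# power for refrigeration; power or an operational flashlight for a light
# source), encoded as extra alternatives inside a group.
#
# These lists are DATA: edit or replace this file to match a local survey
# instrument. The scoring engine hard-codes no resource names.
version: "default-1.0.0"

resources:
  # drugs
  - {resource_id: ampicillin, label: "Ampicillin (parenteral)", category: drug}
  - {resource_id: gentamicin, label: "Gentamicin (parenteral)", category: drug}
  - {resource_id: metronidazole, label: "Metronidazole (parenteral)", category: drug}
  - {resource_id: oxytocin, label: "Oxytocin", category: drug}
  - {resource_id: misoprostol, label: "Misoprostol", category: drug}
  - {resource_id: magnesium_sulfate, label: "Magnesium sulfate", category: drug}
  - {resource_id: calcium_gluconate, label: "Calcium gluconate (MgSO4 antidote)", category: drug}
  - {resource_id: diazepam, label: "Diazepam (second-line anticonvulsant)", category: drug}
  - {resource_id: iv_fluids, label: "IV fluids (crystalloid)", category: drug}
  # consumables
  - {resource_id: iv_cannula, label: "IV cannula / giving set", category: consumable}
  - {resource_id: syringes_needles, label: "Syringes and needles", category: consumable}
  - {resource_id: sterile_gloves, label: "Sterile gloves", category: consumable}
  - {resource_id: urinary_catheter, label: "Urinary catheter", category: consumable}
  - {resource_id: urine_dipstick, label: "Urine protein dipsticks", category: consumable}
  # durable goods
  - {resource_id: bp_apparatus, label: "Blood pressure apparatus", category: durable}
  - {resource_id: stethoscope, label: "Stethoscope", category: durable}
  - {resource_id: thermometer, label: "Thermometer", category: durable}
  - {resource_id: speculum, label: "Vaginal speculum", category: durable}
  - {resource_id: mva_kit, label: "Manual vacuum aspiration kit", category: durable}
  - {resource_id: examination_light, label: "Examination light", category: durable}
  - {resource_id: flashlight, label: "Operational flashlight", category: durable}
  - {resource_id: electricity, label: "Electrical power", category: durable}
  - {resource_id: refrigerator, label: "Refrigerator (drug storage)", category: durable}
  # guidelines and protocols
  - {resource_id: sepsis_protocol, label: "Maternal sepsis management protocol", category: protocol}
  - {resource_id: hypertension_protocol, label: "Severe pre-eclampsia/eclampsia protocol", category: protocol}

cascades:
  - emergency_id: sepsis
    stages:
      identify:
        groups:
          - {alternatives: [thermometer]}
          - {alternatives: [bp_apparatus]}
          - {alternatives: [stethoscope]}
          - {alternatives: [sepsis_protocol]}
      treat:
        groups:
          - {alternatives: [ampicillin]}
          - {alternatives: [gentamicin]}
          - {alternatives: [metronidazole]}
          - {alternatives: [iv_cannula]}
          - {alternatives: [syringes_needles]}
          - {alternatives: [iv_fluids]}
      monitor_modify:
        groups:
          - {alternatives: [thermometer]}
          - {alternatives: [urinary_catheter]}
          - alternatives: [refrigerator, electricity]
            note: "electrical power accepted as proxy for refrigeration"

  - emergency_id: haemorrhage
    stages:
      identify:
        # visual estimation of blood loss: staff skill alone, no commodity
        groups: []
      treat:
        groups:
          - {alternatives: [oxytocin]}
          - {alternatives: [iv_cannula]}
          - {alternatives: [iv_fluids]}
          - {alternatives: [syringes_needles]}
          - {alternatives: [sterile_gloves]}
      monitor_modify:
        groups:
          - {alternatives: [bp_apparatus]}
          - {alternatives: [urinary_catheter]}
          - {alternatives: [misoprostol]}

  - emergency_id: hypertension
    stages:
      identify:
        groups:
          - {alternatives: [bp_apparatus]}
          - {alternatives: [urine_dipstick]}
          - {alternatives: [hypertension_protocol]}
      treat:
        groups:
          - {alternatives: [magnesium_sulfate]}
          - {alternatives: [calcium_gluconate]}
          - {alternatives: [syringes_needles]}
          - {alternatives: [iv_cannula]}
      monitor_modify:
        groups:
          - {alternatives: [stethoscope]}
          - {alternatives: [urinary_catheter]}
          - {alternatives: [diazepam]}

  - emergency_id: retained_placenta
    stages:
      identify:
        # timed absence of placental delivery: staff skill alone
        groups: []
      treat:
        groups:
          - {alternatives: [sterile_gloves]}
          - {alternatives: [oxytocin]}
          - {alternatives: [iv_cannula]}
          - {alternatives: [iv_fluids]}
      monitor_modify:
        groups:
          - {alternatives: [bp_apparatus]}
          - {alternatives: [ampicillin]}
          - {alternatives: [urinary_catheter]}

  - emergency_id: incomplete_abortion
    stages:
      identify:
        groups:
          - {alternatives: [speculum]}
          - alternatives: [examination_light, electricity, flashlight]
            note: "electrical power or operational flashlight accepted as proxy for a light source"
          - {alternatives: [sterile_gloves]}
      treat:
        groups:
          - {alternatives: [mva_kit]}
          - {alternatives: [sterile_gloves]}
          - {alternatives: [iv_fluids]}
      monitor_modify:
        groups:
          - {alternatives: [bp_apparatus]}
          - {alternatives: [oxytocin]}
          - {alternatives: [ampicillin]}

signal_functions:
  - function_id: antibiotic
    function_type: medical_treatment
    linked_emergency_id: sepsis
    tracer_requirement:
      groups:
        - {alternatives: [ampicillin]}
        - {alternatives: [gentamicin]}
        - {alternatives: [metronidazole]}
  - function_id: uterotonic
    function_type: medical_treatment
    linked_emergency_id: haemorrhage
    tracer_requirement:
      groups:
        - {alternatives: [oxytocin]}
  - function_id: anticonvulsant
    function_type: medical_treatment
    linked_emergency_id: hypertension
    tracer_requirement:
      groups:
        - {alternatives: [magnesium_sulfate]}
  - function_id: retained_placenta_removal
    function_type: manual_procedure
    linked_emergency_id: retained_placenta
    tracer_requirement:
      groups:
        - {alternatives: [sterile_gloves]}
        - {alternatives: [oxytocin]}
  - function_id: rpoc_removal
    function_type: manual_procedure
    linked_emergency_id: incomplete_abortion
    tracer_requirement:
      groups:
        - {alternatives: [mva_kit]}
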