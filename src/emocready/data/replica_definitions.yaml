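version: replica-1.0.0
resources:
- resource_id: sepsis_identify_kit
  label: sepsis identify kit
  category: consumable
- resource_id: sepsis_treat_kit
  label: sepsis treat kit
  category: consumable
- resource_id: sepsis_monitor_kit
  label: sepsis monitor kit
  category: consumable
- resource_id: haemorrhage_treat_kit
  label: haemorrhage treat kit
  category: consumable
- resource_id: haemorrhage_monitor_kit
  label: haemorrhage monitor kit
  category: consumable
- resource_id: hypertension_identify_kit
  label: hypertension identify kit
  category: consumable
- resource_id: hypertension_treat_kit
  label: hypertension treat kit
  category: consumable
- resource_id: hypertension_monitor_kit
  label: hypertension monitor kit
  category: consumable
- resource_id: retained_placenta_treat_kit
  label: retained placenta treat kit
  category: consumable
- resource_id: retained_placenta_monitor_kit
  label: retained placenta monitor kit
  category: consumable
- resource_id: incomplete_abortion_identify_kit
  label: incomplete abortion identify kit
  category: consumable
- resource_id: incomplete_abortion_treat_kit
  label: incomplete abortion treat kit
  category: consumable
- resource_id: incomplete_abortion_monitor_kit
  label: incomplete abortion monitor kit
  category: consumable
- resource_id: antibiotic_tracer_kit
  label: antibiotic tracer kit
  category: consumable
- resource_id: uterotonic_tracer_kit
  label: uterotonic tracer kit
  category: consumable
- resource_id: anticonvulsant_tracer_kit
  label: anticonvulsant tracer kit
  category: consumable
- resource_id: retained_placenta_removal_tracer_kit
  label: retained placenta removal tracer kit
  category: consumable
- resource_id: rpoc_removal_tracer_kit
  label: rpoc removal tracer kit
  category: consumable
cascades:
- emergency_id: sepsis
  stages:
    identify:
      skill_only: false
      groups:
      - alternatives:
        - sepsis_identify_kit
    treat:
      skill_only: false
      groups:
      - alternatives:
        - sepsis_treat_kit
    monitor_modify:
      skill_only: false
      groups:
      - alternatives:
        - sepsis_monitor_kit
- emergency_id: haemorrhage
  stages:
    identify:
      skill_only: true
      groups: []
    treat:
      skill_only: false
      groups:
      - alternatives:
        - haemorrhage_treat_kit
    monitor_modify:
      skill_only: false
      groups:
      - alternatives:
        - haemorrhage_monitor_kit
- emergency_id: hypertension
  stages:
    identify:
      skill_only: false
      groups:
      - alternatives:
        - hypertension_identify_kit
    treat:
      skill_only: false
      groups:
      - alternatives:
        - hypertension_treat_kit
    monitor_modify:
      skill_only: false
      groups:
      - alternatives:
        - hypertension_monitor_kit
- emergency_id: retained_placenta
  stages:
    identify:
      skill_only: true
      groups: []
    treat:
      skill_only: false
      groups:
      - alternatives:
        - retained_placenta_treat_kit
    monitor_modify:
      skill_only: false
      groups:
      - alternatives:
        - retained_placenta_monitor_kit
- emergency_id: incomplete_abortion
  stages:
    identify:
      skill_only: false
      groups:
      - alternatives:
        - incomplete_abortion_identify_kit
    treat:
      skill_only: false
      groups:
      - alternatives:
        - incomplete_abortion_treat_kit
    monitor_modify:
      skill_only: false
      groups:
      - alternatives:
        - incomplete_abortion_monitor_kit
signal_functions:
- function_id: antibiotic
  function_type: medical_treatment
  linked_emergency_id: sepsis
  tracer_requirement:
    skill_only: false
    groups:
    - alternatives:
      - antibiotic_tracer_kit
- function_id: uterotonic
  function_type: medical_treatment
  linked_emergency_id: haemorrhage
  tracer_requirement:
    skill_only: false
    groups:
    - alternatives:
      - uterotonic_tracer_kit
- function_id: anticonvulsant
  function_type: medical_treatment
  linked_emergency_id: hypertension
  tracer_requirement:
    skill_only: false
    groups:
    - alternatives:
      - anticonvulsant_tracer_kit
- function_id: retained_placenta_removal
  function_type: manual_procedure
  linked_emergency_id: retained_placenta
  tracer_requirement:
    skill_only: false
    groups:
    - alternatives:
      - retained_placenta_removal_tracer_kit
- function_id: rpoc_removal
  function_type: manual_procedure
  linked_emergency_id: incomplete_abortion
  tracer_requirement:
    skill_only: false
    groups:
    - alternatives:
      - rpoc_removal_tracer_kit
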