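# Illustrative child (1-59 months) expert-algorithm rule set.
#
# PLACEHOLDER CONTENT: simplified, plausible sign/symptom combinations for
# demonstration and testing; substitute transcriptions of published,
# validated algorithms for substantive analyses.
age_group: child
options:
  dont_know_is_no: false
symptoms:
  injury_event: {type: binary, label: Death followed an injury or accident}
  fever: {type: binary, label: Fever}
  fever_days: {type: numeric, unit: days, label: Days of fever}
  rash: {type: binary, label: Rash}
  cough: {type: binary, label: Cough}
  cough_days: {type: numeric, unit: days, label: Days of cough}
  whooping_cough: {type: binary, label: Cough with whoop}
  fast_breathing: {type: binary, label: Fast breathing}
  chest_indrawing: {type: binary, label: Chest indrawing}
  loose_stools: {type: binary, label: Loose or liquid stools}
  stools_per_day: {type: numeric, unit: count, label: Stools in 24 hours}
  bloody_stools: {type: binary, label: Blood in stools}
  stiff_neck: {type: binary, label: Stiff neck}
  bulging_fontanelle: {type: binary, label: Bulging fontanelle}
  convulsions: {type: binary, label: Convulsions}
  unconscious: {type: binary, label: Unconsciousness}
  pallor: {type: binary, label: Severe pallor}
  wasting: {type: binary, label: Severe wasting}
  swollen_feet: {type: binary, label: Swollen feet or legs}
  hiv_positive_mother: {type: binary, label: Mother known HIV positive}
  mouth_sores: {type: binary, label: White mouth sores (thrush)}
  bleeding: {type: binary, label: Bleeding from any site}
rules:
  - cause: injury
    predicate: {symptom: injury_event, response: yes}
  - cause: aids
    predicate:
      all:
        - {symptom: hiv_positive_mother, response: yes}
        - any:
            - {symptom: wasting, response: yes}
            - {symptom: mouth_sores, response: yes}
  - cause: malnutrition_underlying
    predicate:
      all:
        - {symptom: wasting, response: yes}
        - {symptom: swollen_feet, response: yes}
  - cause: measles
    predicate:
      all:
        - {symptom: fever, response: yes}
        - {symptom: rash, response: yes}
  - cause: meningitis
    predicate:
      all:
        - {symptom: fever, response: yes}
        - any:
            - {symptom: stiff_neck, response: yes}
            - {symptom: bulging_fontanelle, response: yes}
  - cause: dysentery
    predicate:
      all:
        - {symptom: loose_stools, response: yes}
        - {symptom: bloody_stools, response: yes}
  - cause: diarrhea
    predicate:
      all:
        - {symptom: loose_stools, response: yes}
        - {symptom: stools_per_day, op: ge, value: 6}
        - {symptom: bloody_stools, response: no}
  - cause: pertussis
    predicate:
      all:
        - {symptom: whooping_cough, response: yes}
        - {symptom: cough_days, op: ge, value: 14}
  - cause: pneumonia
    predicate:
      all:
        - {symptom: cough, response: yes}
        - {symptom: fast_breathing, response: yes}
        - {symptom: chest_indrawing, response: yes}
  - cause: malaria
    predicate:
      all:
        - {symptom: fever, response: yes}
        - any:
            - {symptom: convulsions, response: yes}
            - {symptom: pallor, response: yes}
        - {symptom: stiff_neck, response: no}
        - {symptom: rash, response: no}
  - cause: possible_dysentery
    predicate:
      all:
        - {symptom: bloody_stools, response: yes}
        - {symptom: loose_stools, response: no}
  - cause: possible_diarrhea
    predicate:
      all:
        - {symptom: loose_stools, response: yes}
        - {symptom: stools_per_day, op: le, value: 5}
        - {symptom: bloody_stools, response: no}
  - cause: possible_pneumonia
    predicate:
      all:
        - {symptom: cough, response: yes}
        - {symptom: fast_breathing, response: yes}
        - {symptom: chest_indrawing, response: no}
  - cause: hemorrhagic_fever
    predicate:
      all:
        - {symptom: fever, response: yes}
        - {symptom: bleeding, response: yes}
  - cause: other_infection
    predicate:
      all:
        - {symptom: fever, response: yes}
        - {symptom: fever_days, op: ge, value: 14}
  - cause: residual_infection
    predicate:
      all:
        - {symptom: fever, response: yes}
        - {symptom: unconscious, response: yes}
        - {symptom: stiff_neck, response: no}
  - cause: malnutrition
    predicate:
      all:
        - {symptom: wasting, response: yes}
        - {symptom: swollen_feet, response: no}
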