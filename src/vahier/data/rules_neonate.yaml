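# Illustrative neonatal expert-algorithm rule set.
#
# PLACEHOLDER CONTENT: the predicates below are simplified, plausible
# sign/symptom combinations intended for demonstration and testing. Published,
# validated algorithm definitions should be transcribed into this same schema
# by the user before any substantive analysis.
age_group: neonate
options:
  dont_know_is_no: false
symptoms:
  born_early: {type: binary, label: Born before 9 months of pregnancy}
  gestation_months: {type: numeric, unit: months, label: Months of pregnancy at birth}
  not_cried_at_birth: {type: binary, label: Did not cry after birth}
  not_breathed_at_birth: {type: binary, label: Did not breathe after birth}
  malformation: {type: binary, label: Visible malformation at birth}
  spasms: {type: binary, label: Spasms or convulsions}
  stopped_suckling: {type: binary, label: Stopped suckling after having suckled}
  fever: {type: binary, label: Fever}
  cold_to_touch: {type: binary, label: Cold to the touch}
  lethargic: {type: binary, label: Lethargic or unconscious}
  bulging_fontanelle: {type: binary, label: Bulging fontanelle}
  fast_breathing: {type: binary, label: Fast breathing}
  chest_indrawing: {type: binary, label: Chest indrawing}
  grunting: {type: binary, label: Grunting}
  loose_stools: {type: binary, label: Loose or liquid stools}
  stools_per_day: {type: numeric, unit: count, label: Stools in 24 hours}
  yellow_skin: {type: binary, label: Yellow skin or eyes}
  bleeding: {type: binary, label: Bleeding from any site}
  delivery_injury: {type: binary, label: Bruising or injury from delivery}
  well_then_died: {type: binary, label: Appeared well then died suddenly}
rules:
  - cause: neonatal_tetanus
    predicate:
      all:
        - {symptom: stopped_suckling, response: yes}
        - {symptom: spasms, response: yes}
  - cause: congenital_malformation
    predicate: {symptom: malformation, response: yes}
  - cause: birth_injury
    predicate: {symptom: delivery_injury, response: yes}
  - cause: birth_asphyxia
    predicate:
      any:
        - {symptom: not_cried_at_birth, response: yes}
        - {symptom: not_breathed_at_birth, response: yes}
  - cause: meningitis
    predicate:
      all:
        - {symptom: fever, response: yes}
        - {symptom: bulging_fontanelle, response: yes}
  - cause: diarrhea
    predicate:
      all:
        - {symptom: loose_stools, response: yes}
        - {symptom: stools_per_day, op: ge, value: 6}
  - cause: pneumonia
    predicate:
      all:
        - {symptom: fast_breathing, response: yes}
        - any:
            - {symptom: chest_indrawing, response: yes}
            - {symptom: grunting, response: yes}
  - cause: possible_diarrhea
    predicate:
      all:
        - {symptom: loose_stools, response: yes}
        - {symptom: stools_per_day, op: le, value: 5}
  - cause: possible_pneumonia
    predicate:
      all:
        - {symptom: fast_breathing, response: yes}
        - {symptom: chest_indrawing, response: no}
        - {symptom: grunting, response: no}
  - cause: sepsis
    predicate:
      all:
        - any:
            - {symptom: fever, response: yes}
            - {symptom: cold_to_touch, response: yes}
        - any:
            - {symptom: stopped_suckling, response: yes}
            - {symptom: lethargic, response: yes}
  - cause: jaundice
    predicate: {symptom: yellow_skin, response: yes}
  - cause: hemorrhagic_disease
    predicate: {symptom: bleeding, response: yes}
  - cause: sudden_unexplained_death
    predicate: {symptom: well_then_died, response: yes}
  - cause: preterm_delivery
    predicate:
      any:
        - {symptom: born_early, response: yes}
        - {symptom: gestation_months, op: le, value: 8}
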