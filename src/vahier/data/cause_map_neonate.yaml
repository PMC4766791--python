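# Neonatal reference-standard harmonization and VA cause grouping.
#
# direct: single reference causes -> harmonized underlying cause (conditions
#   directly due to prematurity, e.g. respiratory distress syndrome, map to
#   preterm delivery).
# comorbid: exact co-morbid reference sets; the three-way set is split
#   proportionally over sepsis and birth asphyxia according to the deaths
#   already singly assigned to those causes.
# groups: VA output causes collapsed into their scoring counterparts.
direct:
  congenital_malformation: congenital_malformation
  birth_asphyxia: birth_asphyxia
  meningitis: meningitis
  pneumonia: pneumonia
  sepsis: sepsis
  sepsis_with_local_bacterial_infection: sepsis
  preterm_delivery: preterm_delivery
  preterm_delivery_rds: preterm_delivery
comorbid:
  - pattern: [preterm_delivery, birth_asphyxia]
    target: birth_asphyxia
  - pattern: [preterm_delivery, sepsis]
    target: sepsis
  - pattern: [preterm_delivery, sepsis, birth_asphyxia]
    proportional_over: [sepsis, birth_asphyxia]
groups:
  possible_pneumonia: pneumonia
  possible_diarrhea: diarrhea
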