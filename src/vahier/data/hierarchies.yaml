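# Bundled cause-assignment hierarchies.
#
# Each hierarchy is an ordered list of rank levels; a level may hold several
# causes tied at that level (resolved left-to-right). Published hierarchies
# name some causes with umbrella labels ("ARI", "other causes", "other
# possible serious infections"); here every level is spelled out against the
# shared VA cause vocabulary so that the same rule set can be scored under
# every hierarchy. Causes a hierarchy does not rank are listed under
# fallback_causes and resolve to the fallback ("unspecified") when nothing
# ranked fires.
neonate:
  arifeen:
    ranks:
      - [neonatal_tetanus]
      - [congenital_malformation]
      - [birth_asphyxia]
      - [birth_injury]
      - [pneumonia, diarrhea]                      # "ARI, diarrhea"
      - [possible_diarrhea, possible_pneumonia, sepsis]
      - [preterm_delivery]
      # "other causes" bucket
      - [meningitis, jaundice, hemorrhagic_disease, sudden_unexplained_death]
    fallback: unspecified
  baqui:
    ranks:
      - [neonatal_tetanus, congenital_malformation]
      - [preterm_delivery]
      - [birth_asphyxia]
      - [birth_injury]
      - [sepsis, pneumonia]
      - [diarrhea]
    fallback: unspecified
    fallback_causes:
      [meningitis, possible_diarrhea, possible_pneumonia, jaundice,
       hemorrhagic_disease, sudden_unexplained_death]
  kalter:
    ranks:
      - [neonatal_tetanus]
      - [congenital_malformation]
      - [birth_asphyxia, birth_injury]
      - [meningitis]
      - [diarrhea]
      - [pneumonia]
      - [possible_diarrhea]
      - [possible_pneumonia]
      - [sepsis]
      - [jaundice]
      - [hemorrhagic_disease]
      - [sudden_unexplained_death]
      - [preterm_delivery]
    fallback: unspecified
  lawn:
    ranks:
      - [congenital_malformation]
      - [neonatal_tetanus]
      - [preterm_delivery]
      - [birth_asphyxia]
      - [sepsis, pneumonia, meningitis]
      - [diarrhea]
      # "other" bucket
      - [birth_injury, possible_diarrhea, possible_pneumonia, jaundice,
         hemorrhagic_disease, sudden_unexplained_death]
    fallback: unspecified
  liu:
    ranks:
      - [neonatal_tetanus]
      - [congenital_malformation]
      - [birth_asphyxia, birth_injury]
      - [diarrhea, pneumonia]                      # "diarrhea, ARI"
      - [meningitis]
      - [possible_pneumonia, possible_diarrhea]
      - [preterm_delivery]
      # "sepsis, other possible serious infections"
      - [sepsis, jaundice, hemorrhagic_disease, sudden_unexplained_death]
    fallback: unspecified
  compromise:
    ranks:
      - [congenital_malformation]
      - [birth_asphyxia]
      - [preterm_delivery]
      - [sepsis, pneumonia, meningitis]
    fallback: unspecified
    fallback_causes:
      [neonatal_tetanus, birth_injury, diarrhea, possible_diarrhea,
       possible_pneumonia, jaundice, hemorrhagic_disease,
       sudden_unexplained_death]
child:
  arifeen:
    ranks:
      - [injury]
      - [pneumonia, diarrhea, measles]             # "ARI, diarrhea, measles"
      # "possible serious infections" bucket
      - [meningitis, dysentery, pertussis, malaria, aids,
         possible_pneumonia, possible_diarrhea, possible_dysentery,
         hemorrhagic_fever, other_infection, residual_infection]
      - [malnutrition]
      - [malnutrition_underlying]                  # "other causes"
    fallback: unspecified
  kalter:
    ranks:
      - [injury]
      - [aids]
      - [malnutrition_underlying]
      - [measles]
      - [meningitis]
      - [dysentery]
      - [diarrhea]
      - [pertussis]
      - [pneumonia]
      - [malaria]
      - [possible_dysentery]
      - [possible_diarrhea]
      - [possible_pneumonia]
      - [hemorrhagic_fever]
      - [other_infection]
      - [residual_infection]
      - [malnutrition]
    fallback: unspecified
  liu:
    ranks:
      - [injury]
      - [measles, diarrhea, pneumonia]             # "measles, diarrhea, ARI"
      - [meningitis]
      - [malaria]
      - [aids]
      - [possible_diarrhea, possible_pneumonia, possible_dysentery]
      # "other possible serious infections" bucket
      - [dysentery, pertussis, hemorrhagic_fever, other_infection,
         residual_infection, malnutrition, malnutrition_underlying]
    fallback: unspecified
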