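# Child (1-59 months) reference-standard harmonization and VA cause grouping.
#
# Reference injuries are recorded by mechanism and mapped directly to
# "injury"; co-morbid pneumonia/diarrhea deaths are split proportionally over
# the two causes; "possible" VA causes collapse into their definite
# counterparts, residual infection scores as possible malaria, and the
# miscellaneous infections score as "other_infectious".
direct:
  bite_venomous_animal: injury
  burn: injury
  drowning: injury
  fall: injury
  poisoning: injury
  road_traffic: injury
  violent_death: injury
  aids: aids
  measles: measles
  encephalitis: meningitis
  meningitis: meningitis
  diarrhea: diarrhea
  dysentery: diarrhea
  pneumonia: pneumonia
  malaria: malaria
  hemorrhagic_fever: other_infectious
  sepsis: other_infectious
  tuberculosis: other_infectious
  other_infectious: other_infectious
  non_infectious: non_infectious
comorbid:
  - pattern: [pneumonia, diarrhea]
    proportional_over: [pneumonia, diarrhea]
groups:
  dysentery: diarrhea
  possible_dysentery: diarrhea
  possible_diarrhea: diarrhea
  possible_pneumonia: pneumonia
  residual_infection: malaria
  pertussis: other_infectious
  hemorrhagic_fever: other_infectious
  other_infection: other_infectious
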