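# Stock and cohort functional-group definitions.
# One document per table; column names mirror the group-definition tables.

stock_functional_groups:
  - Realm: Marine
    Nutrition Source: Photosynthesis
    Mobility: Planktonic
    Leaf Strategy: N/A
  - Realm: Terrestrial
    Nutrition Source: Photosynthesis
    Mobility: Sessile
    Leaf Strategy: Deciduous
  - Realm: Terrestrial
    Nutrition Source: Photosynthesis
    Mobility: Sessile
    Leaf Strategy: Evergreen

cohort_functional_groups:
  - {Realm: Marine, Feeding Mode: Herbivore, Mobility: Planktonic, Reproductive Strategy: Iteroparity, Thermoregulation Mode: Ectotherm, Log10 Minimum Mass for Functional Group (kg): -8.00, Log10 Maximum Mass for Functional Group (kg): -4.00, Herbivory Proportional Assimilation Efficiency: 0.7, Carnivory Proportional Assimilation Efficiency: 0.0}
  - {Realm: Marine, Feeding Mode: Herbivore, Mobility: Planktonic, Reproductive Strategy: Semelparity, Thermoregulation Mode: Ectotherm, Log10 Minimum Mass for Functional Group (kg): -8.00, Log10 Maximum Mass for Functional Group (kg): -4.00, Herbivory Proportional Assimilation Efficiency: 0.7, Carnivory Proportional Assimilation Efficiency: 0.0}
  - {Realm: Marine, Feeding Mode: Herbivore, Mobility: Mobile, Reproductive Strategy: Iteroparity, Thermoregulation Mode: Ectotherm, Log10 Minimum Mass for Functional Group (kg): -7.00, Log10 Maximum Mass for Functional Group (kg): 1.00, Herbivory Proportional Assimilation Efficiency: 0.7, Carnivory Proportional Assimilation Efficiency: 0.0}
  - {Realm: Marine, Feeding Mode: Herbivore, Mobility: Mobile, Reproductive Strategy: Semelparity, Thermoregulation Mode: Ectotherm, Log10 Minimum Mass for Functional Group (kg): -7.00, Log10 Maximum Mass for Functional Group (kg): 1.00, Herbivory Proportional Assimilation Efficiency: 0.7, Carnivory Proportional Assimilation Efficiency: 0.0}
  - {Realm: Marine, Feeding Mode: Omnivore, Mobility: Mobile, Reproductive Strategy: Iteroparity, Thermoregulation Mode: Endotherm, Log10 Minimum Mass for Functional Group (kg): 1.00, Log10 Maximum Mass for Functional Group (kg): 5.18, Herbivory Proportional Assimilation Efficiency: 0.0, Carnivory Proportional Assimilation Efficiency: 0.8}
  - {Realm: Marine, Feeding Mode: Omnivore, Mobility: Mobile, Reproductive Strategy: Iteroparity, Thermoregulation Mode: Ectotherm, Log10 Minimum Mass for Functional Group (kg): -8.00, Log10 Maximum Mass for Functional Group (kg): 2.00, Herbivory Proportional Assimilation Efficiency: 0.6, Carnivory Proportional Assimilation Efficiency: 0.64}
  - {Realm: Marine, Feeding Mode: Omnivore, Mobility: Mobile, Reproductive Strategy: Semelparity, Thermoregulation Mode: Ectotherm, Log10 Minimum Mass for Functional Group (kg): -8.00, Log10 Maximum Mass for Functional Group (kg): 2.00, Herbivory Proportional Assimilation Efficiency: 0.6, Carnivory Proportional Assimilation Efficiency: 0.64}
  - {Realm: Marine, Feeding Mode: Carnivore, Mobility: Mobile, Reproductive Strategy: Iteroparity, Thermoregulation Mode: Endotherm, Log10 Minimum Mass for Functional Group (kg): -1.00, Log10 Maximum Mass for Functional Group (kg): 4.70, Herbivory Proportional Assimilation Efficiency: 0.0, Carnivory Proportional Assimilation Efficiency: 0.8}
  - {Realm: Marine, Feeding Mode: Carnivore, Mobility: Mobile, Reproductive Strategy: Iteroparity, Thermoregulation Mode: Ectotherm, Log10 Minimum Mass for Functional Group (kg): -7.00, Log10 Maximum Mass for Functional Group (kg): 3.30, Herbivory Proportional Assimilation Efficiency: 0.0, Carnivory Proportional Assimilation Efficiency: 0.8}
  - {Realm: Marine, Feeding Mode: Carnivore, Mobility: Mobile, Reproductive Strategy: Semelparity, Thermoregulation Mode: Ectotherm, Log10 Minimum Mass for Functional Group (kg): -7.00, Log10 Maximum Mass for Functional Group (kg): 3.30, Herbivory Proportional Assimilation Efficiency: 0.0, Carnivory Proportional Assimilation Efficiency: 0.8}
  - {Realm: Terrestrial, Feeding Mode: Herbivore, Mobility: Mobile, Reproductive Strategy: Iteroparity, Thermoregulation Mode: Endotherm, Log10 Minimum Mass for Functional Group (kg): -2.82, Log10 Maximum Mass for Functional Group (kg): 3.70, Herbivory Proportional Assimilation Efficiency: 0.5, Carnivory Proportional Assimilation Efficiency: 0.0}
  - {Realm: Terrestrial, Feeding Mode: Herbivore, Mobility: Mobile, Reproductive Strategy: Semelparity, Thermoregulation Mode: Ectotherm, Log10 Minimum Mass for Functional Group (kg): -6.40, Log10 Maximum Mass for Functional Group (kg): 0.00, Herbivory Proportional Assimilation Efficiency: 0.5, Carnivory Proportional Assimilation Efficiency: 0.0}
  - {Realm: Terrestrial, Feeding Mode: Herbivore, Mobility: Mobile, Reproductive Strategy: Iteroparity, Thermoregulation Mode: Ectotherm, Log10 Minimum Mass for Functional Group (kg): -3.00, Log10 Maximum Mass for Functional Group (kg): 2.48, Herbivory Proportional Assimilation Efficiency: 0.5, Carnivory Proportional Assimilation Efficiency: 0.0}
  - {Realm: Terrestrial, Feeding Mode: Omnivore, Mobility: Mobile, Reproductive Strategy: Iteroparity, Thermoregulation Mode: Endotherm, Log10 Minimum Mass for Functional Group (kg): -2.52, Log10 Maximum Mass for Functional Group (kg): 3.18, Herbivory Proportional Assimilation Efficiency: 0.4, Carnivory Proportional Assimilation Efficiency: 0.64}
  - {Realm: Terrestrial, Feeding Mode: Omnivore, Mobility: Mobile, Reproductive Strategy: Semelparity, Thermoregulation Mode: Ectotherm, Log10 Minimum Mass for Functional Group (kg): -6.40, Log10 Maximum Mass for Functional Group (kg): 0.30, Herbivory Proportional Assimilation Efficiency: 0.4, Carnivory Proportional Assimilation Efficiency: 0.64}
  - {Realm: Terrestrial, Feeding Mode: Omnivore, Mobility: Mobile, Reproductive Strategy: Iteroparity, Thermoregulation Mode: Ectotherm, Log10 Minimum Mass for Functional Group (kg): -2.82, Log10 Maximum Mass for Functional Group (kg): 1.74, Herbivory Proportional Assimilation Efficiency: 0.4, Carnivory Proportional Assimilation Efficiency: 0.64}
  - {Realm: Terrestrial, Feeding Mode: Carnivore, Mobility: Mobile, Reproductive Strategy: Iteroparity, Thermoregulation Mode: Endotherm, Log10 Minimum Mass for Functional Group (kg): -2.52, Log10 Maximum Mass for Functional Group (kg): 2.85, Herbivory Proportional Assimilation Efficiency: 0.0, Carnivory Proportional Assimilation Efficiency: 0.8}
  - {Realm: Terrestrial, Feeding Mode: Carnivore, Mobility: Mobile, Reproductive Strategy: Semelparity, Thermoregulation Mode: Ectotherm, Log10 Minimum Mass for Functional Group (kg): -6.10, Log10 Maximum Mass for Functional Group (kg): 0.30, Herbivory Proportional Assimilation Efficiency: 0.0, Carnivory Proportional Assimilation Efficiency: 0.8}
  - {Realm: Terrestrial, Feeding Mode: Carnivore, Mobility: Mobile, Reproductive Strategy: Iteroparity, Thermoregulation Mode: Ectotherm, Log10 Minimum Mass for Functional Group (kg): -2.82, Log10 Maximum Mass for Functional Group (kg): 3.30, Herbivory Proportional Assimilation Efficiency: 0.0, Carnivory Proportional Assimilation Efficiency: 0.8}
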