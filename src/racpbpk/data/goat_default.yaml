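# Default goat / ractopamine configuration.
#
# Organ weight and blood-flow fractions and the drug-specific constants are
# the model's reference values for a ~30 kg male Cashmere goat; cardiac
# output, brain/spleen perfusion, blood volume and its arterial split, the
# vascular fractions of the membrane-limited tissues, the hematocrit and the
# plasma free fraction are package defaults from the small-ruminant PBPK
# literature (see docs/methods.md) and are freely configurable.
physiology:
  body_mass: 30.0            # kg
  cardiac_output: 5.97       # L/h per kg BW
  organ_mass_fraction:       # fraction of body weight (density 1 kg/L)
    liver: 0.0129
    kidney: 0.0031
    muscle: 0.3527
    lungs: 0.0078
    fat: 0.0274
    brain: 0.0032
    spleen: 0.0028
    heart: 0.0035
    rest: 0.5866             # blood volume is carved out of this at resolve time
  organ_flow_fraction:       # fraction of cardiac output; liver = total hepatic inflow
    liver: 0.4832
    kidney: 0.1705
    muscle: 0.14
    fat: 0.085
    heart: 0.0498
    rest: 0.0715             # brain flow is carved out of this
  brain_flow_fraction: 0.02
  spleen_flow_fraction: 0.02 # routed through the liver inflow
  blood_volume_fraction: 0.07
  arterial_fraction: 0.3333333333333333
  tissue_blood_fraction:
    muscle: 0.04
    fat: 0.02
    brain: 0.04
    rest: 0.04
  hematocrit: 0.30
  blood_plasma_ratio: 1.0    # plasma output = venous blood concentration / ratio
drug:
  partition:                 # tissue : plasma, dimensionless
    liver: 2.5584
    kidney: 1.7734
    spleen: 1.0047
    heart: 1.3839
    lung: 1.5333
    muscle: 1.0686
    fat: 0.7526
    brain: 0.6896
    rest: 9.0888
  permeability_fraction:     # Pa_i = fraction x Q_i (flow-scaled convention)
    muscle: 0.0271
    fat: 0.0054
    brain: 0.0068
    rest: 0.0021
  permeability_absolute: false
  cl_hepatic: 0.0624         # L/h per kg BW
  cl_renal: 0.0001           # L/h per kg BW
  k_stomach: 0.0910          # 1/h gastric emptying
  k_absorption: 0.9861       # 1/h intestinal absorption
  k_gut: 0.9016              # 1/h fecal loss
  free_fraction: 1.0
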