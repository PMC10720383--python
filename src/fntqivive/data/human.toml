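# Default human parameterization (reference adult, 60 kg).
#
# Oral absorption (fa, ka_s, ka_i, ks_i), GFR, microsomal protein yield and
# plasma protein concentration are literature reference values.  Physiology
# uses standard reference human values and is overridable per file.
#
# Compound binding/partitioning and the Michaelis-Menten constants are
# SYNTHETIC stand-ins chosen once to respect the qualitative interspecies
# picture: the human CYP450 bioactivation efficiency is 6.4-fold lower than
# the rat's, detoxification efficiencies are comparable between species, and
# PON1 hydrolysis is slower in humans.  They are not measured values.

[species]
species_label = "human"
body_weight = 60.0
cardiac_output = 310.0
hematocrit = 0.44
fa = 0.7
ka_s = 0.32
ka_i = 0.59
ks_i = 0.48
gfr = 1.8
microsomal_yield = 32.0
plasma_protein_conc = 66.0

[species.tissue_volume_fractions]
liver = 0.026
kidney = 0.004
fat = 0.214
blood = 0.079
rapidly_perfused = 0.05
slowly_perfused = 0.561

[species.tissue_flow_fractions]
liver = 0.227
kidney = 0.175
fat = 0.052
rapidly_perfused = 0.296
slowly_perfused = 0.25

[[compounds]]
compound_label = "FNT"
molecular_weight = 277.23
fup = 0.05
bpr = 0.55
[compounds.partition_blood]
liver = 4.0
kidney = 3.5
fat = 100.0
rapidly_perfused = 4.0
slowly_perfused = 2.0

[[compounds]]
compound_label = "FNO"
molecular_weight = 261.17
fup = 0.15
bpr = 0.55
[compounds.partition_blood]
liver = 2.5
kidney = 2.0
fat = 15.0
rapidly_perfused = 2.5
slowly_perfused = 1.5

[[compounds]]
compound_label = "MNP"
molecular_weight = 153.14
fup = 0.3
bpr = 0.55
[compounds.partition_blood]
liver = 1.5
kidney = 1.2
fat = 3.0
rapidly_perfused = 1.5
slowly_perfused = 1.0

# In vitro Michaelis-Menten constants (vmax in nmol/min/mg protein, km in uM).
[kinetics.FNT_to_FNO]
vmax = 0.5
km = 40.0
matrix = "liver_microsomes"

[kinetics.FNT_to_MNP]
vmax = 0.6
km = 30.0
matrix = "liver_microsomes"

[kinetics.FNO_to_MNP_liver]
vmax = 3.0
km = 1500.0
matrix = "liver_microsomes"

[kinetics.FNO_to_MNP_blood]
vmax = 0.25
km = 1500.0
matrix = "plasma"
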