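# Default rat parameterization.
#
# Oral absorption (fa, ka_s, ka_i, ks_i), GFR, microsomal protein yield and
# plasma protein concentration are literature reference values.  Physiology
# (volume/flow fractions, cardiac output, hematocrit) uses standard reference
# rat values (Brown et al.-style) and is overridable per file.
#
# Compound binding/partitioning and the Michaelis-Menten constants are
# SYNTHETIC stand-ins: plausible values consistent with each compound's
# lipophilicity class and with the qualitative kinetic picture (bioactivation
# faster than detoxification, rat:human bioactivation efficiency ratio 6.4,
# hydrolysis Km in the thousands of uM).  They are not measured values.

[species]
species_label = "rat"
body_weight = 0.25
cardiac_output = 5.4
hematocrit = 0.46
fa = 0.9
ka_s = 0.1
ka_i = 0.59
ks_i = 0.48
gfr = 5.2
microsomal_yield = 35.0
plasma_protein_conc = 59.0

[species.tissue_volume_fractions]
liver = 0.034
kidney = 0.007
fat = 0.07
blood = 0.074
rapidly_perfused = 0.05
slowly_perfused = 0.676

[species.tissue_flow_fractions]
liver = 0.183
kidney = 0.141
fat = 0.07
rapidly_perfused = 0.356
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
vmax = 1.6
km = 20.0
matrix = "liver_microsomes"

[kinetics.FNT_to_MNP]
vmax = 0.8
km = 40.0
matrix = "liver_microsomes"

[kinetics.FNO_to_MNP_liver]
vmax = 6.0
km = 1500.0
matrix = "liver_microsomes"

[kinetics.FNO_to_MNP_blood]
vmax = 0.5
km = 1500.0
matrix = "plasma"
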