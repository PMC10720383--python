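"""The complete two-species QIVIVE pipeline in one call.

Runs kinetics fitting, IVIVE scaling, PBK simulation with a 2-fold
evaluation, AChE curve fitting, reverse dosimetry and BMD analysis for rat
and human, and prints the species points of departure and their ratio.
"""

import fntqivive as fq

record = fq.run_pipeline({
    "run": {"species": ["rat", "human"], "seed": 1},
    "qivive": {"n_grid": 20},
    "bmd": {"n_bootstrap": 500},
})

for species in ("rat", "human"):
    r = record.species_results[species]
    print(f"{species}:")
    print(f"  IC50 (FNO, blood)    = {r['ic50_uM']:.3f} uM (hill {r['hill']:.2f})")
    print(f"  evaluation max fold  = {r['evaluation_max_fold']:.2f}")
    print(f"  BMD10 / BMDL10       = {r['bmd10']:.3f} / {r['bmdl10']:.3f} mg/kg BW "
          f"({r['bmd_model_family']})")
print(f"rat:human BMDL10 ratio = {record.bmdl_ratio:.2f}")
# A ratio above 1 means the human point of departure is lower, i.e. humans
# are predicted to be more susceptible to acute FNT exposure.
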