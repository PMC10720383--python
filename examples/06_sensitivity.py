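"""Local sensitivity analysis of the Cmax blood FNO dose metric.

Perturbs each model parameter by +5% (one at a time) and reports the
normalized sensitivity coefficients at a low oral dose, plus a 2-fold
evaluation of model predictions against noisy synthetic observations.
"""

import numpy as np

import fntqivive as fq

sp, compounds, kin_vitro = fq.load_defaults("rat")
model = fq.build_model(sp, compounds, fq.scale_kinetics(kin_vitro, sp))
regimen = fq.DosingRegimen(route="oral", dose=1.0)

params = ["dose", "species.fa", "species.cardiac_output", "species.hematocrit",
          "species.microsomal_yield", "species.gfr",
          "kinetics.FNT_to_FNO.vmax", "kinetics.FNO_to_MNP_liver.vmax",
          "compounds.FNO.fup", "compounds.FNO.partition_blood.fat"]
report = fq.local_sensitivity(model, regimen, parameters=params,
                              invitro_kinetics=kin_vitro)
print("normalized sensitivity of Cmax blood FNO (top first):")
for name, sc in report.coefficients.items():
    print(f"  {name:40s} {sc:+.3f}")

# 2-fold evaluation against synthetic in vivo observations (30% CV)
obs = fq.gen_invivo_timecourse(model, regimen, np.linspace(1, 24, 8),
                               cv=0.30, seed=3)
comp = fq.fold_difference(obs["true_value"], obs["observed"])
print(f"max fold difference vs observations: {comp.folds.max():.2f} "
      f"(2-fold rule {'passed' if comp.passed else 'failed'})")
# |SC| near 1 means proportional influence; coefficients near 0 mark
# parameters the dose metric barely depends on.  At 30% CV an occasional
# observation can exceed the 2-fold band — the evaluation reports it honestly.
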