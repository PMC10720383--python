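"""Published points of departure for acute fenitrothion exposure.

Reported regulatory NOAELs and the QIVIVE-predicted BMDL10 values
(mg/kg BW, erythrocyte AChE inhibition endpoint) are carried as inputs so
that fold comparisons between PODs can be computed reproducibly.
"""

from __future__ import annotations

#: Regulatory no-observed-adverse-effect levels, mg/kg BW.
REPORTED_NOAELS = {
    ("rat", "US EPA"): 0.25,
    ("rat", "EFSA"): 1.30,
    ("human", "APVMA"): 0.33,
    ("human", "JMPR"): 0.36,
}

#: QIVIVE-predicted BMDL10 points of departure, mg/kg BW.
REPORTED_BMDL10 = {"rat": 1.30, "human": 0.26}


def pod_fold_ratio(a: float, b: float) -> float:
    """Symmetric fold ratio max(a/b, b/a) between two PODs."""
    if not (a > 0 and b > 0):
        raise ValueError("PODs must be strictly positive")
    return max(a / b, b / a)


def reported_bmdl_species_ratio() -> float:
    """Fold difference between the reported rat and human BMDL10 PODs."""
    return pod_fold_ratio(REPORTED_BMDL10["rat"], REPORTED_BMDL10["human"])


def reported_rat_noael_ratio() -> float:
    """Fold difference between the EFSA and US EPA rat NOAELs."""
    return pod_fold_ratio(REPORTED_NOAELS[("rat", "EFSA")],
                          REPORTED_NOAELS[("rat", "US EPA")])
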