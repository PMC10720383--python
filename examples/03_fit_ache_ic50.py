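"""Fit blood AChE inhibition curves and extract species IC50s.

Generates synthetic rat-like (plateau-then-drop) and human-like
(progressive-decline) AChE activity data for the oxon metabolite FNO and
fits the four-parameter log-logistic curve to each.
"""

import fntqivive as fq

for preset in ("rat_like", "human_like"):
    data = fq.gen_ache_cr(preset=preset, seed=7)
    fit = fq.fit_concentration_response(data)
    print(f"{preset:11s}: IC50 = {fq.ic50(fit):.3f} uM, hill = {fit.hill:.2f}, "
          f"top = {fit.top:.1f}%, bottom = {fit.bottom:.1f}%")
# Both species inhibit near 1 uM FNO, but the rat curve is much steeper
# (high Hill) — the low-dose region differs, which later drives the
# species difference in the benchmark dose.
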