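"""Benchmark-dose fitting, closed-form BMD and confidence limits."""

import math

import numpy as np
import pytest

import fntqivive as fq
from fntqivive.bmd import _exp3, _exp4, _hill4
from fntqivive.errors import DomainError, InsufficientRangeError
from fntqivive.qivive import DoseResponseCurve


def _curve(dose, response):
    return DoseResponseCurve(dose=np.asarray(dose, float),
                             response=np.asarray(response, float),
                             provenance=["grid"] * len(dose), species_label="rat")


DOSES = np.geomspace(0.05, 50.0, 25)


class TestFit:
    def test_noise_free_exp3_recovery(self):
        y = _exp3(DOSES, 100.0, 0.2, 1.3)
        fit = fq.fit_bmd_model(_curve(DOSES, y), "exponential-3")
        assert fit.params["a"] == pytest.approx(100.0, rel=1e-6)
        assert fit.params["b"] == pytest.approx(0.2, rel=1e-5)
        assert fit.params["g"] == pytest.approx(1.3, rel=1e-5)

    def test_constant_response_insufficient_range(self):
        with pytest.raises(InsufficientRangeError):
            fq.fit_bmd_model(_curve(DOSES, np.full(len(DOSES), 90.0)), "exponential-3")

    def test_too_few_points(self):
        with pytest.raises(InsufficientRangeError):
            fq.fit_bmd_model(_curve([0.1, 1.0, 10.0], [100.0, 60.0, 10.0]),
                             "exponential-3")

    def test_aic_selects_hill_on_hill_data(self):
        """Model selection: seeded Hill-shaped data prefer the hill-4 family."""
        rng = np.random.default_rng(17)
        y = _hill4(DOSES, 100.0, 0.05, 2.0, 3.0) + rng.normal(0, 1.0, len(DOSES))
        fits = {fam: fq.fit_bmd_model(_curve(DOSES, y), fam)
                for fam in ("exponential-3", "exponential-4", "hill-4")}
        best = min(fits.values(), key=lambda f: f.aic)
        assert best.family == "hill-4"


class TestBMD:
    def test_closed_form_exponential_decay(self):
        """y = 100·e^(−0.1·d) → BMD10 = ln(1/0.9)/0.1."""
        y = _exp3(DOSES, 100.0, 0.1, 1.0)
        fit = fq.fit_bmd_model(_curve(DOSES, y), "exponential-3")
        assert fq.compute_bmd(fit, bmr=0.10) == pytest.approx(
            math.log(1 / 0.9) / 0.1, rel=1e-6)

    def test_bmr_to_zero_limit(self):
        y = _exp3(DOSES, 100.0, 0.1, 1.0)
        fit = fq.fit_bmd_model(_curve(DOSES, y), "exponential-3")
        assert fq.compute_bmd(fit, bmr=1e-9) < 1e-6

    @pytest.mark.parametrize("family,params", [
        ("exponential-3", {"a": 100.0, "b": 0.15, "g": 1.7}),
        ("exponential-4", {"a": 100.0, "b": 0.4, "c": 0.2}),
        ("hill-4", {"a": 100.0, "c": 0.1, "k": 2.0, "g": 2.5}),
    ])
    def test_root_finding_matches_closed_form(self, family, params):
        func = {"exponential-3": _exp3, "exponential-4": _exp4, "hill-4": _hill4}[family]
        y = func(DOSES, **params)
        fit = fq.fit_bmd_model(_curve(DOSES, y), family)
        closed = fq.compute_bmd(fit, 0.10)
        root = fq.compute_bmd(fit, 0.10, method="root")
        assert root == pytest.approx(closed, rel=1e-9)

    def test_invalid_bmr_rejected(self):
        y = _exp3(DOSES, 100.0, 0.1, 1.0)
        fit = fq.fit_bmd_model(_curve(DOSES, y), "exponential-3")
        with pytest.raises(DomainError):
            fq.compute_bmd(fit, bmr=1.5)

    def test_invariant_under_response_rescaling(self):
        """BMD uses a relative deviation, so scaling the response axis by a
        constant leaves it unchanged."""
        rng = np.random.default_rng(3)
        y = _exp3(DOSES, 100.0, 0.12, 1.4) + rng.normal(0, 1.5, len(DOSES))
        f1 = fq.fit_bmd_model(_curve(DOSES, y), "exponential-3")
        f2 = fq.fit_bmd_model(_curve(DOSES, 3.7 * y), "exponential-3")
        assert fq.compute_bmd(f2) == pytest.approx(fq.compute_bmd(f1), rel=1e-5)


class TestBMDL:
    def test_zero_noise_degenerate(self):
        y = _exp3(DOSES, 100.0, 0.1, 1.0)
        fit = fq.fit_bmd_model(_curve(DOSES, y), "exponential-3")
        bmdl, bmdu, _ = fq.compute_bmdl(fit, n_bootstrap=200, seed=1)
        bmd = fq.compute_bmd(fit)
        assert bmdl == pytest.approx(bmd, rel=1e-6)
        assert bmdu == pytest.approx(bmd, rel=1e-6)

    def test_bootstrap_widens_with_noise(self):
        """BMDL is non-increasing as injected noise grows (seeded scan)."""
        bmdls = []
        for sigma in (0.5, 2.0, 6.0):
            rng = np.random.default_rng(42)
            y = _exp3(DOSES, 100.0, 0.1, 1.0) + rng.normal(0, sigma, len(DOSES))
            fit = fq.fit_bmd_model(_curve(DOSES, y), "exponential-3")
            bmdl, _, _ = fq.compute_bmdl(fit, n_bootstrap=300, seed=7)
            bmdls.append(bmdl)
        assert bmdls[0] > bmdls[1] > bmdls[2]

    def test_ordering_invariant(self):
        rng = np.random.default_rng(9)
        for seed in range(5):
            y = _exp3(DOSES, 100.0, 0.1, 1.2) + rng.normal(0, 3.0, len(DOSES))
            fit = fq.fit_bmd_model(_curve(DOSES, y), "exponential-3")
            bmd = fq.compute_bmd(fit)
            bmdl, bmdu, _ = fq.compute_bmdl(fit, n_bootstrap=200, seed=seed)
            assert 0 < bmdl <= bmd <= bmdu

    def test_profile_likelihood_brackets_bmd(self):
        rng = np.random.default_rng(21)
        y = _exp3(DOSES, 100.0, 0.1, 1.0) + rng.normal(0, 2.0, len(DOSES))
        fit = fq.fit_bmd_model(_curve(DOSES, y), "exponential-3")
        bmd = fq.compute_bmd(fit)
        bmdl, bmdu, _ = fq.compute_bmdl(fit, ci_method="profile_likelihood")
        assert 0 < bmdl < bmd < bmdu

    def test_bootstrap_floor_enforced(self):
        y = _exp3(DOSES, 100.0, 0.1, 1.0)
        fit = fq.fit_bmd_model(_curve(DOSES, y), "exponential-3")
        with pytest.raises(DomainError):
            fq.compute_bmdl(fit, n_bootstrap=50)


def test_bmd_analysis_end_to_end_selection():
    rng = np.random.default_rng(4)
    y = _exp4(DOSES, 100.0, 0.3, 0.15) + rng.normal(0, 1.0, len(DOSES))
    res = fq.bmd_analysis(_curve(DOSES, y), n_bootstrap=200, seed=5)
    assert res.model_family in ("exponential-3", "exponential-4", "hill-4")
    assert 0 < res.bmdl <= res.bmd <= res.bmdu
    assert res.bmr == 0.10
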