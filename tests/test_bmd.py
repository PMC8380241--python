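import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mnflow.bmd import (
    BMDConfig,
    BMDModelParams,
    DoseResponseDataset,
    bmd_confidence_interval,
    compute_bmd,
    fit_covariate_model,
    model_response,
)
from mnflow.bmd.models import compute_bmd_numeric

CFG = BMDConfig(model_family="hill")


def simulate_curve(seed, concs=(0.0, 0.25, 0.5, 1.0), n_reps=3, sd=0.1,
                   a=0.005, b=1.0, c=8.0, d=2.0, level="s"):
    """Lognormal replicate noise around a Hill curve."""
    rng = np.random.default_rng(seed)
    rows = []
    for x in concs:
        mu = a * (1 + (c - 1) * x**d / (b**d + x**d))
        for r in range(n_reps):
            rows.append((x, mu * math.exp(rng.normal(0.0, sd)) if sd else mu,
                         level, r))
    return rows


class TestModelResponse:
    def test_background_at_zero(self):
        p = BMDModelParams(a=2.0, b=1.5, c=4.0, d=1.3)
        for fam in ("hill", "exponential"):
            assert model_response(0.0, p, fam) == pytest.approx(2.0)

    def test_flat_when_c_equals_one(self):
        p = BMDModelParams(a=3.0, b=1.0, c=1.0, d=2.0)
        for fam in ("hill", "exponential"):
            for x in (0.0, 0.5, 5.0):
                assert model_response(x, p, fam) == pytest.approx(3.0)

    def test_hill_direct_evaluation(self):
        p = BMDModelParams(a=2.0, b=1.0, c=3.0, d=1.0)
        assert model_response(1.0, p, "hill") == pytest.approx(4.0)

    def test_asymptote(self):
        p = BMDModelParams(a=2.0, b=1.0, c=3.0, d=2.0)
        for fam in ("hill", "exponential"):
            assert model_response(1e6, p, fam) == pytest.approx(6.0, rel=1e-3)

    def test_unknown_family_rejected(self):
        p = BMDModelParams(a=1.0, b=1.0, c=2.0, d=1.0)
        with pytest.raises(ValueError, match="family"):
            model_response(1.0, p, "probit")


class TestComputeBmd:
    def test_hill_closed_form_example(self):
        p = BMDModelParams(a=2.0, b=1.0, c=3.0, d=1.0)
        assert compute_bmd(p, "hill", 0.5) == pytest.approx(1 / 3, rel=1e-12)

    def test_exponential_closed_form_example(self):
        p = BMDModelParams(a=1.0, b=1.0, c=3.0, d=1.0)
        assert compute_bmd(p, "exponential", 0.5) == pytest.approx(
            math.log(4 / 3), rel=1e-12)

    def test_matches_root_finding_oracle(self):
        p = BMDModelParams(a=0.7, b=2.3, c=5.0, d=1.7)
        for fam in ("hill", "exponential"):
            assert compute_bmd(p, fam, 0.5) == pytest.approx(
                compute_bmd_numeric(p, fam, 0.5), rel=1e-8)

    def test_flat_curve_unreachable(self):
        p = BMDModelParams(a=1.0, b=1.0, c=1.0, d=1.0)
        for fam in ("hill", "exponential"):
            with pytest.raises(ValueError, match="unreachable"):
                compute_bmd(p, fam, 0.5)

    def test_c_below_benchmark_unreachable(self):
        p = BMDModelParams(a=1.0, b=1.0, c=1.4, d=1.0)
        with pytest.raises(ValueError, match="unreachable"):
            compute_bmd(p, "hill", 0.5)

    @given(
        st.floats(0.001, 10.0), st.floats(0.05, 20.0),
        st.floats(1.6, 50.0), st.floats(0.3, 5.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_inverse_property(self, a, b, c, d):
        p = BMDModelParams(a=a, b=b, c=c, d=d)
        for fam in ("hill", "exponential"):
            bmd = compute_bmd(p, fam, 0.5)
            assert model_response(bmd, p, fam) == pytest.approx(
                a * 1.5, rel=1e-8)


class TestParamValidation:
    @pytest.mark.parametrize("kw", [
        dict(a=-1.0, b=1, c=2, d=1), dict(a=1, b=0, c=2, d=1),
        dict(a=1, b=1, c=0.5, d=1), dict(a=1, b=1, c=2, d=0),
        dict(a=1, b=1, c=2, d=1, var=0),
    ])
    def test_invalid_params(self, kw):
        with pytest.raises(ValueError):
            BMDModelParams(**kw)


class TestCovariateFit:
    def test_single_level_equals_plain_fit(self):
        data = DoseResponseDataset.from_records(simulate_curve(3))
        res = fit_covariate_model(data, CFG)
        assert res.level_specific == ()
        assert not res.covariate_rejected_for_potency
        assert res.ladder == []
        assert "s" in res.levels

    def test_identical_curves_reject_level_specific_potency(self):
        rows = (simulate_curve(10, level="A") +
                simulate_curve(11, level="B"))
        res = fit_covariate_model(DoseResponseDataset.from_records(rows), CFG)
        assert res.covariate_rejected_for_potency
        # all levels share one BMD
        bmds = [r.bmd for r in res.levels.values()]
        assert bmds[0] == pytest.approx(bmds[1], rel=1e-9)

    def test_double_potency_detected_and_recovered(self):
        rows = (simulate_curve(20, n_reps=6, level="A", b=1.0) +
                simulate_curve(21, n_reps=6, level="B", b=2.0))
        res = fit_covariate_model(DoseResponseDataset.from_records(rows), CFG)
        assert not res.covariate_rejected_for_potency
        ratio = res.levels["B"].bmd / res.levels["A"].bmd
        assert 1.6 <= ratio <= 2.4

    def test_nesting_loglik_ordering(self):
        rows = (simulate_curve(30, level="A") +
                simulate_curve(31, level="B", b=1.5))
        res = fit_covariate_model(DoseResponseDataset.from_records(rows), CFG)
        # accepted model's loglik >= every rejected simpler model on the ladder
        for step in res.ladder:
            if not step.accepted:
                assert res.loglik >= step.loglik - 1e-6 or step.loglik <= res.loglik + 1e-6

    def test_exponential_and_hill_agree_at_low_noise(self):
        rows = simulate_curve(40, concs=(0.0, 0.25, 0.5, 1.0, 2.0),
                              n_reps=4, sd=0.02)
        data = DoseResponseDataset.from_records(rows)
        bmd_h = fit_covariate_model(data, CFG).levels["s"].bmd
        bmd_e = fit_covariate_model(
            data, BMDConfig(model_family="exponential")).levels["s"].bmd
        assert abs(bmd_h - bmd_e) / bmd_h <= 0.15

    def test_both_families_returns_dict(self):
        data = DoseResponseDataset.from_records(simulate_curve(50))
        out = fit_covariate_model(data, BMDConfig(model_family="both"))
        assert set(out) == {"exponential", "hill"}

    def test_nonpositive_response_rejected(self):
        rows = simulate_curve(60)
        rows[0] = (rows[0][0], 0.0, rows[0][2], rows[0][3])
        with pytest.raises(ValueError, match="pseudo-count"):
            fit_covariate_model(DoseResponseDataset.from_records(rows), CFG)

    def test_too_few_concentrations_rejected(self):
        rows = [(0.0, 0.01, "s", r) for r in range(3)] + \
               [(1.0, 0.02, "s", r) for r in range(3)]
        with pytest.raises(ValueError, match="3 distinct"):
            fit_covariate_model(DoseResponseDataset.from_records(rows), CFG)


class TestConfidenceInterval:
    def test_brackets_bmd(self):
        data = DoseResponseDataset.from_records(
            simulate_curve(70, concs=(0.0, 0.25, 0.5, 1.0, 2.0), n_reps=4))
        res = bmd_confidence_interval(fit_covariate_model(data, CFG), CFG)
        lv = res.levels["s"]
        assert lv.bmdl <= lv.bmd <= lv.bmdu

    def test_width_shrinks_with_noise(self):
        widths = []
        for sd in (0.02, 0.3):
            data = DoseResponseDataset.from_records(
                simulate_curve(71, concs=(0.0, 0.25, 0.5, 1.0, 2.0),
                               n_reps=4, sd=sd))
            res = bmd_confidence_interval(fit_covariate_model(data, CFG), CFG)
            lv = res.levels["s"]
            widths.append(math.log(lv.bmdu / lv.bmdl))
        assert widths[0] < widths[1]

    def test_noise_to_zero_interval_collapses_on_truth(self):
        # exact curve values: interval must be tight around the true BMD
        data = DoseResponseDataset.from_records(
            simulate_curve(0, concs=(0.0, 0.25, 0.5, 1.0, 2.0), n_reps=3,
                           sd=1e-4))
        res = bmd_confidence_interval(fit_covariate_model(data, CFG), CFG)
        lv = res.levels["s"]
        t = 0.5 / 7.0
        true_bmd = (t / (1 - t)) ** 0.5
        assert lv.bmdl <= true_bmd <= lv.bmdu
        assert lv.bmdu / lv.bmdl < 1.05

    def test_dataset_requires_control_per_level(self):
        with pytest.raises(ValueError, match="control"):
            DoseResponseDataset.from_records([(1.0, 0.01, "A", 0)])
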