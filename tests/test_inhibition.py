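"""ThT pipeline: normalization, sequential fits, potency metric."""

import numpy as np
import pytest

from amytrap.aggregation import apply_inhibitor, half_time, simulate_auto
from amytrap.inhibition import (
    ThTDataset,
    ThTValidationError,
    Trace,
    fit_secondary_modulation,
    fit_uninhibited,
    normalize_tht,
    potency_concentration,
    predict_sequestration_only,
)
from amytrap.synthetic import default_aggregation_parameters, gen_tht_dataset

KD = 83e-9
TRUE_FACTORS = {0.5e-6: 0.5, 1e-6: 0.2}


@pytest.fixture(scope="module")
def noisy_dataset():
    return gen_tht_dataset(
        seed=42,
        binder_kd=KD,
        binder_concs=(0.0, 0.5e-6, 1e-6),
        k2_factors=TRUE_FACTORS,
        noise_sigma=0.02,
    )


@pytest.fixture(scope="module")
def noiseless_dataset():
    return gen_tht_dataset(
        seed=0,
        binder_kd=KD,
        binder_concs=(0.0, 0.5e-6, 1e-6),
        k2_factors=TRUE_FACTORS,
        noise_sigma=0.0,
    )


@pytest.fixture(scope="module")
def uninhibited_fit(noisy_dataset):
    return fit_uninhibited(normalize_tht(noisy_dataset))


class TestNormalize:
    def test_affine_invariance(self, noiseless_dataset):
        """Normalizing a*M(t)+b gives the same curve as normalizing M(t)."""
        truth = noiseless_dataset.ground_truth
        a, b = truth["signal_a"], truth["signal_b"]
        raw = noiseless_dataset.traces_at(0.0)[0]
        m_curve = (raw.f - b) / a  # undo the affine signal map -> M(t)
        plain = ThTDataset(traces={(0.0, 0): Trace(raw.t, m_curve)}, monomer_conc=2e-6)
        norm_signal = normalize_tht(noiseless_dataset).traces_at(0.0)[0]
        norm_plain = normalize_tht(plain).traces_at(0.0)[0]
        assert np.allclose(norm_signal.f, norm_plain.f, atol=1e-9)
        # and the normalized curve tracks fraction aggregated to high accuracy
        frac = m_curve / m_curve[-1]
        assert np.allclose(norm_signal.f, frac, atol=1e-3)

    def test_idempotent(self, noisy_dataset):
        once = normalize_tht(noisy_dataset)
        assert normalize_tht(once) is once

    def test_flat_trace_flagged_no_aggregation(self, noisy_dataset):
        ds = ThTDataset(
            traces={
                (0.0, 0): noisy_dataset.traces[(0.0, 0)],
                (2e-6, 0): Trace(
                    noisy_dataset.traces[(0.0, 0)].t,
                    np.full_like(noisy_dataset.traces[(0.0, 0)].f, 10.0),
                ),
            },
            monomer_conc=2e-6,
        )
        norm = normalize_tht(ds)
        assert "no_aggregation" in norm.flags[(2e-6, 0)]
        assert np.all(norm.traces[(2e-6, 0)].f == 0.0)

    def test_short_trace_rejected(self):
        with pytest.raises(ThTValidationError):
            normalize_tht(
                ThTDataset(
                    traces={(0.0, 0): Trace(np.arange(5.0), np.arange(5.0))},
                    monomer_conc=2e-6,
                )
            )

    def test_output_within_unit_band(self, noisy_dataset):
        norm = normalize_tht(noisy_dataset)
        for tr in norm.traces.values():
            assert tr.f.min() > -0.2 and tr.f.max() < 1.2


class TestUninhibitedFit:
    def test_noiseless_rate_product_recovery(self, noiseless_dataset):
        truth = noiseless_dataset.ground_truth["params"]
        fit = fit_uninhibited(normalize_tht(noiseless_dataset))
        assert fit.kn_kplus == pytest.approx(truth.kn * truth.kplus, rel=0.01)
        assert fit.k2_kplus == pytest.approx(truth.k2 * truth.kplus, rel=0.01)

    def test_fit_beats_primary_only_model(self, noiseless_dataset):
        """The generating (secondary-nucleation) model fits better than k2=0."""
        from dataclasses import replace

        from amytrap.aggregation import simulate
        from amytrap.inhibition import _normalized_model_curve

        norm = normalize_tht(noiseless_dataset)
        fit = fit_uninhibited(norm)
        tr = norm.traces_at(0.0)[0]
        full = _normalized_model_curve(fit.params(), tr.t, self_normalized=True)
        no_k2 = _normalized_model_curve(
            replace(fit.params(), k2=0.0), tr.t, self_normalized=True
        )
        assert np.linalg.norm(full - tr.f) < np.linalg.norm(no_k2 - tr.f)

    def test_missing_uninhibited_trace_rejected(self, noisy_dataset):
        inhibited_only = {k: v for k, v in noisy_dataset.traces.items() if k[0] > 0}
        with pytest.raises(ThTValidationError):
            ThTDataset(traces=inhibited_only, monomer_conc=2e-6)


class TestSequestrationOnly:
    def test_zero_conc_is_uninhibited_curve(self, uninhibited_fit):
        pred = predict_sequestration_only(uninhibited_fit, KD, [0.0])
        curve = pred[0.0]["curve"]
        assert pred[0.0]["m_eff"] == pytest.approx(uninhibited_fit.monomer_conc)
        assert curve[-1] == pytest.approx(1.0, rel=1e-3)

    def test_curves_shift_right_with_binder(self, uninhibited_fit):
        pred = predict_sequestration_only(uninhibited_fit, KD, [0.0, 0.5e-6, 1e-6])
        halves = [
            half_time(
                simulate_auto(
                    uninhibited_fit.params(m_total=pred[c]["m_eff"])
                )
            )
            for c in (0.0, 0.5e-6, 1e-6)
        ]
        assert halves[0] < halves[1] < halves[2]

    def test_missing_kd_raises_pointer_to_mds(self, uninhibited_fit):
        with pytest.raises(ThTValidationError, match="fit_mds_quadratic"):
            predict_sequestration_only(uninhibited_fit, None, [1e-6])

    def test_insufficiency_quantified(self, noisy_dataset, uninhibited_fit):
        """On data with real k2 suppression, sequestration alone fits worse."""
        norm = normalize_tht(noisy_dataset)
        seq = predict_sequestration_only(
            uninhibited_fit, KD, list(TRUE_FACTORS), dataset=norm
        )
        full = fit_secondary_modulation(norm, uninhibited_fit, binder_kd=KD)
        for conc in TRUE_FACTORS:
            assert seq[conc]["residual_norm"] >= full.residual_norms[conc]


class TestModulationFit:
    def test_recovery_of_generating_factors(self, noisy_dataset, uninhibited_fit):
        result = fit_secondary_modulation(
            normalize_tht(noisy_dataset), uninhibited_fit, binder_kd=KD
        )
        for conc, truth in TRUE_FACTORS.items():
            assert result.k2_factors[conc] == pytest.approx(truth, rel=0.15)

    def test_factor_near_one_on_sequestration_only_data(self):
        ds = gen_tht_dataset(
            seed=5,
            binder_kd=KD,
            binder_concs=(0.0, 0.5e-6),
            k2_factors=None,  # truth: no secondary-nucleation suppression
            noise_sigma=0.0,
        )
        fit = fit_uninhibited(normalize_tht(ds))
        result = fit_secondary_modulation(normalize_tht(ds), fit, binder_kd=KD)
        assert result.k2_factors[0.5e-6] > 0.95

    def test_high_bound_fraction_excluded_and_flagged(self, uninhibited_fit):
        ds = gen_tht_dataset(
            seed=9,
            binder_kd=1e-10,  # very tight binder: >90% of monomer bound at 2 uM
            binder_concs=(0.0, 2e-6),
            noise_sigma=0.0,
        )
        norm = normalize_tht(ds)
        fit = fit_uninhibited(norm)
        result = fit_secondary_modulation(norm, fit, binder_kd=1e-10)
        assert result.excluded_concs == [2e-6]
        assert 2e-6 not in result.k2_factors
        assert any(
            "excluded_bound_fraction" in fl
            for key, fl in norm.flags.items()
            if key[0] == 2e-6
        )

    def test_no_inhibited_traces_rejected(self, uninhibited_fit):
        ds = gen_tht_dataset(seed=1, binder_concs=(0.0,), noise_sigma=0.0)
        with pytest.raises(ThTValidationError):
            fit_secondary_modulation(normalize_tht(ds), uninhibited_fit, binder_kd=KD)


class TestPotency:
    def test_zero_increase_is_zero_concentration(self, uninhibited_fit):
        assert potency_concentration(uninhibited_fit, KD, increase=0.0) == 0.0

    def test_bisection_matches_dense_grid(self, uninhibited_fit):
        pot = potency_concentration(uninhibited_fit, KD)
        base = uninhibited_fit.params()
        t0 = half_time(simulate_auto(base))
        concs = np.logspace(np.log10(pot) - 0.3, np.log10(pot) + 0.3, 41)
        ratios = []
        for c in concs:
            from amytrap.aggregation import InhibitorModel

            eff = apply_inhibitor(
                base, InhibitorModel(binder_kd=KD, binder_conc=float(c))
            )
            ratios.append(half_time(simulate_auto(eff)) / t0)
        grid_pot = np.interp(1.5, ratios, concs)
        assert pot == pytest.approx(grid_pot, rel=0.01)

    def test_tighter_binder_never_less_potent(self, uninhibited_fit):
        weak = potency_concentration(uninhibited_fit, 755e-9)
        strong = potency_concentration(uninhibited_fit, 83e-9)
        assert strong <= weak

    def test_not_reached_returns_none(self, uninhibited_fit):
        # cap the search so the 50% slowdown cannot be reached
        assert (
            potency_concentration(
                uninhibited_fit, KD, conc_bounds=(1e-12, 1e-9)
            )
            is None
        )

    def test_ordering_matches_inhibition_strength(self, uninhibited_fit):
        """Tighter Kd + stronger k2 suppression => lower potency concentration."""
        binders = {
            "strong": (83e-9, 0.2e-6),
            "mid": (350e-9, 0.6e-6),
            "weak": (755e-9, 2.5e-6),
        }
        pots = {
            name: potency_concentration(
                uninhibited_fit, kd, modulation=lambda c, ki=ki: 1.0 / (1.0 + c / ki)
            )
            for name, (kd, ki) in binders.items()
        }
        assert pots["strong"] < pots["mid"] < pots["weak"]
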