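"""1:1 binding models: closed forms vs independent oracles, fit recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from amytrap.binding_models import (
    BindingParameters,
    BindingValidationError,
    EquilibriumSystem,
    association_trace,
    complex_conc_quadratic,
    dissociation_trace,
    fit_kinetic_global,
    fit_mds_quadratic,
    fit_steady_state,
    free_monomer,
    steady_state_response,
)
from amytrap.synthetic import gen_bli_dataset, gen_mds_dataset


def bisect_complex(l_tot, b_tot, kd):
    """Independent mass-balance oracle: root of (L-C)(B-C) = Kd*C."""
    if l_tot == 0 or b_tot == 0:
        return 0.0
    f = lambda c: (l_tot - c) * (b_tot - c) - kd * c
    return brentq(f, 0.0, min(l_tot, b_tot), xtol=1e-30, rtol=1e-15)


class TestQuadratic:
    def test_no_binder_no_complex(self):
        assert complex_conc_quadratic(EquilibriumSystem(1e-6, 0.0, 1e-9)) == 0.0

    def test_symmetric_closed_form(self):
        """L = B = Kd gives C = Kd(3 - sqrt(5))/2."""
        kd = 3.7e-8
        c = complex_conc_quadratic(EquilibriumSystem(kd, kd, kd))
        assert c == pytest.approx(kd * (3.0 - math.sqrt(5.0)) / 2.0, rel=1e-12)

    def test_free_monomer_at_printed_affinity(self):
        """2 uM monomer + 1 uM binder at Kd = 83 nM leaves ~1.07 uM free."""
        sys = EquilibriumSystem(l_tot=2e-6, b_tot=1e-6, kd=83e-9)
        free = free_monomer(sys)
        assert free == pytest.approx(2e-6 - bisect_complex(2e-6, 1e-6, 83e-9), rel=1e-9)
        assert free == pytest.approx(1.07e-6, rel=0.01)

    def test_agrees_with_bisection_over_random_systems(self, rng):
        for _ in range(2000):
            l_tot = 10.0 ** rng.uniform(-12, -3)
            b_tot = 10.0 ** rng.uniform(-12, -3)
            kd = 10.0 ** rng.uniform(-12, -3)
            c = complex_conc_quadratic(EquilibriumSystem(l_tot, b_tot, kd))
            assert c == pytest.approx(
                bisect_complex(l_tot, b_tot, kd), rel=1e-9, abs=1e-10 * 1e-3
            )
            assert 0.0 <= c <= min(l_tot, b_tot)

    def test_free_monomer_limits(self):
        assert free_monomer(EquilibriumSystem(1e-6, 0.0, 1e-9)) == 1e-6
        # weak binding: Kd enormous -> essentially all free
        weak = free_monomer(EquilibriumSystem(1e-6, 1e-6, 1e3))
        assert weak == pytest.approx(1e-6, rel=1e-6)
        # saturation: binder excess, tight Kd -> essentially none free
        sat = free_monomer(EquilibriumSystem(1e-9, 1e-3, 1e-15))
        assert sat < 1e-14

    def test_negative_inputs_rejected(self):
        with pytest.raises(BindingValidationError):
            EquilibriumSystem(-1e-6, 1e-6, 1e-9)
        with pytest.raises(BindingValidationError):
            EquilibriumSystem(1e-6, 1e-6, 0.0)


class TestParameters:
    def test_kd_filled_from_rates(self):
        p = BindingParameters(kon=1e4, koff=1e-3)
        assert p.kd == pytest.approx(1e-7, rel=1e-12)

    def test_inconsistent_kd_rejected(self):
        with pytest.raises(BindingValidationError):
            BindingParameters(kon=1e4, koff=1e-3, kd=2e-7)

    def test_nonpositive_rejected(self):
        with pytest.raises(BindingValidationError):
            BindingParameters(kon=0.0)


class TestResponses:
    def test_steady_state_anchor_points(self):
        p = BindingParameters(kd=1e-7, rmax=2.0)
        assert steady_state_response(0.0, p) == 0.0
        assert steady_state_response(1e-7, p) == pytest.approx(1.0)
        assert steady_state_response(3e-7, p) == pytest.approx(1.5)

    def test_steady_state_monotone_in_conc_and_affinity(self):
        conc = np.logspace(-9, -5, 40)
        p = BindingParameters(kd=1e-7, rmax=1.0)
        r = steady_state_response(conc, p)
        assert np.all(np.diff(r) > 0)
        tighter = steady_state_response(conc, BindingParameters(kd=1e-8, rmax=1.0))
        assert np.all(tighter > r)

    def test_association_matches_ode_oracle(self, rng):
        """Closed form vs numerical integration of dR/dt = kon*C*(Rmax-R) - koff*R."""
        for _ in range(5):
            p = BindingParameters(
                kon=10.0 ** rng.uniform(2, 5),
                koff=10.0 ** rng.uniform(-4, -1),
                rmax=rng.uniform(0.5, 3.0),
            )
            conc = p.kd * 10.0 ** rng.uniform(-1, 1)
            t = np.linspace(0.0, 3.0 / (p.kon * conc + p.koff), 50)
            sol = solve_ivp(
                lambda _t, r: p.kon * conc * (p.rmax - r) - p.koff * r,
                (0, t[-1]),
                [0.0],
                t_eval=t,
                rtol=1e-12,
                atol=1e-14,
            )
            closed = association_trace(t, conc, p)
            scale = p.rmax * conc / (conc + p.kd)
            assert np.allclose(closed, sol.y[0], rtol=0, atol=1e-8 * scale)

    def test_phase_boundaries(self):
        p = BindingParameters(kon=1e4, koff=1e-3, rmax=1.0)
        assert association_trace([0.0], 1e-7, p)[0] == 0.0
        assert dissociation_trace([0.0], 0.4, p)[0] == 0.4
        req = steady_state_response(1e-7, p)
        assert association_trace([1e7], 1e-7, p)[0] == pytest.approx(req)

    def test_negative_time_rejected(self):
        p = BindingParameters(kon=1e4, koff=1e-3, rmax=1.0)
        with pytest.raises(BindingValidationError):
            association_trace([-1.0, 0.0], 1e-7, p)


class TestSteadyStateFit:
    def test_noiseless_recovery_exact(self):
        """Noiseless titration generated at Kd = 2 uM refits to 2 uM."""
        kd, rmax = 2e-6, 1.3
        conc = np.logspace(-8, -4, 10)
        data = pd.DataFrame(
            {
                "conc_M": conc,
                "response": steady_state_response(
                    conc, BindingParameters(kd=kd, rmax=rmax)
                ),
            }
        )
        fit = fit_steady_state(data)
        assert fit.params["kd"] == pytest.approx(kd, rel=1e-6)
        assert fit.params["rmax"] == pytest.approx(rmax, rel=1e-6)

    def test_too_few_concentrations_rejected(self):
        data = pd.DataFrame({"conc_M": [1e-9, 1e-8, 1e-7], "response": [0.1, 0.3, 0.6]})
        with pytest.raises(BindingValidationError):
            fit_steady_state(data)

    def test_saturated_design_flagged(self):
        kd = 1e-9
        conc = np.logspace(-7, -4, 8)  # all >> Kd
        data = pd.DataFrame(
            {
                "conc_M": conc,
                "response": steady_state_response(
                    conc, BindingParameters(kd=kd, rmax=1.0)
                ),
            }
        )
        fit = fit_steady_state(data)
        assert any("poorly identified" in w for w in fit.warnings)


class TestKineticFit:
    def test_noiseless_global_recovery(self):
        truth = BindingParameters(kon=1e4, koff=1e-3, rmax=1.0)
        ds = gen_bli_dataset(seed=0, p=truth, noise_sigma=0.0)
        fit = fit_kinetic_global(ds.data)
        assert fit.params["kon"] == pytest.approx(truth.kon, rel=1e-6)
        assert fit.params["koff"] == pytest.approx(truth.koff, rel=1e-6)
        assert fit.params["kd"] == pytest.approx(truth.kd, rel=1e-6)

    def test_noisy_recovery_within_5pct_median(self):
        truth = BindingParameters(kon=1e4, koff=1e-3, rmax=1.0)
        kds = []
        for seed in range(25):
            ds = gen_bli_dataset(seed=seed, p=truth, noise_sigma=0.01, dt=5.0)
            kds.append(fit_kinetic_global(ds.data).params["kd"])
        assert np.median(kds) == pytest.approx(truth.kd, rel=0.05)


class TestMDSFit:
    def test_noiseless_recovery_exact(self):
        for kd in (83e-9, 2e-6):
            ds = gen_mds_dataset(seed=0, kd=kd, noise_sigma=0.0)
            fit = fit_mds_quadratic(ds.data, l_tot=ds.truth["l_tot"])
            assert fit.params["kd"] == pytest.approx(kd, rel=1e-6)

    def test_radius_readout_joint_fit(self):
        ds = gen_mds_dataset(
            seed=1, kd=350e-9, noise_sigma=0.0, rh_free=1.8, rh_complex=3.4
        )
        fit = fit_mds_quadratic(ds.data, l_tot=ds.truth["l_tot"])
        assert fit.params["kd"] == pytest.approx(350e-9, rel=1e-4)
        assert fit.params["rh_free"] == pytest.approx(1.8, rel=1e-3)
        assert fit.params["rh_complex"] == pytest.approx(3.4, rel=1e-3)

    def test_monte_carlo_recovery_83nM(self):
        """sigma = 0.03, triplicates: median fitted Kd within 20% of 83 nM."""
        kds = [
            fit_mds_quadratic(
                gen_mds_dataset(seed=seed, kd=83e-9).data, l_tot=10e-9
            ).params["kd"]
            for seed in range(50)
        ]
        assert np.median(kds) == pytest.approx(83e-9, rel=0.20)

    def test_bias_vanishes_with_noise(self):
        errs = []
        for sigma in (0.05, 0.005):
            kds = [
                fit_mds_quadratic(
                    gen_mds_dataset(seed=s, kd=200e-9, noise_sigma=sigma).data,
                    l_tot=10e-9,
                ).params["kd"]
                for s in range(12)
            ]
            errs.append(abs(np.median(kds) / 200e-9 - 1.0))
        assert errs[1] < errs[0]
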