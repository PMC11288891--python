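"""Moment-equation model of amyloid fibril formation and its inhibition.

The forward model is the standard two-moment description of filamentous
self-assembly with primary nucleation, elongation and fibril-surface
(secondary) nucleation.  With ``P`` the fibril number concentration, ``M``
the fibril mass concentration and ``m = m_total - M`` the free monomer:

    dP/dt = kn * m**nc  +  k2 * m**n2 * M
    dM/dt = 2 * kplus * m * P

The factor 2 reflects growth at both fibril ends.  For Aβ42 the secondary
pathway dominates, making aggregation autocatalytic and giving the
characteristic sigmoidal ThT curves.  The system is integrated numerically,
which covers seeded and inhibited cases uniformly; the closed-form
early-time limit ``M(t) ~ kn*kplus*m_total**(nc+1)*t**2`` (for k2 = 0,
unseeded) serves as an analytic check, not as the implementation.

Inhibition enters through two couplings:

* **monomer sequestration** — binder-bound monomer is treated as removed
  from the reaction, so the effective initial monomer is the free-monomer
  root of the 1:1 depletion quadratic, computed once at t = 0 (dissociation
  of the monomer-binder complex is ignored over the aggregation timescale);
* **secondary-nucleation suppression** — ``k2`` is scaled by a
  concentration-dependent factor in (0, 1], either tabulated per binder
  concentration or parametric, ``1 / (1 + [I]/K_I)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
from scipy.integrate import solve_ivp

from amytrap.binding_models import EquilibriumSystem, free_monomer

__all__ = [
    "AggregationParameters",
    "InhibitorModel",
    "Trajectory",
    "simulate",
    "simulate_auto",
    "simulate_with_inhibitor",
    "half_time",
    "curve_half_time",
    "half_time_scaling",
    "IncompleteCurveError",
    "SimulationError",
]


class AggregationValidationError(ValueError):
    """Invalid aggregation-model inputs."""


class SimulationError(RuntimeError):
    """The stiff solver failed; the message echoes the parameters."""


class IncompleteCurveError(ValueError):
    """The trajectory has not reached its plateau; half-time undefined."""


@dataclass(frozen=True)
class AggregationParameters:
    """Rate constants and initial condition of the aggregation network.

    Units: ``kn`` M^(1-nc) s^-1, ``kplus`` M^-1 s^-1, ``k2`` M^-n2 s^-1,
    concentrations molar.  ``M0``/``P0`` seed the reaction (0 = unseeded).
    ``growth_ends`` is the number of growth-competent fibril ends (2 by
    convention: both ends elongate).
    """

    kn: float
    kplus: float
    k2: float
    m_total: float
    nc: float = 2.0
    n2: float = 2.0
    m0: float = 0.0
    p0: float = 0.0
    growth_ends: float = 2.0

    def __post_init__(self) -> None:
        for name in ("kn", "kplus", "k2", "m0", "p0"):
            if getattr(self, name) < 0:
                raise AggregationValidationError(f"{name} must be >= 0")
        if self.nc < 1 or self.n2 < 1:
            raise AggregationValidationError("reaction orders nc, n2 must be >= 1")
        if not self.m_total > 0:
            raise AggregationValidationError("m_total must be > 0")
        if self.m0 > self.m_total:
            raise AggregationValidationError("seed mass M0 cannot exceed m_total")
        if self.growth_ends <= 0:
            raise AggregationValidationError("growth_ends must be > 0")


@dataclass(frozen=True)
class InhibitorModel:
    """Coupling of a monomer-binding inhibitor to the aggregation network.

    ``binder_kd`` and ``binder_conc`` (molar) set the sequestration
    equilibrium.  The secondary-nucleation modulation factor is either
    tabulated per binder concentration (``k2_factors``; looked up with
    log-linear interpolation for intermediate concentrations) or parametric
    via ``ki``: factor = 1 / (1 + conc/ki).  With neither given the factor
    is 1 (sequestration-only).
    """

    binder_kd: float
    binder_conc: float
    k2_factors: Mapping[float, float] | None = None
    ki: float | None = None

    def __post_init__(self) -> None:
        if not self.binder_kd > 0:
            raise AggregationValidationError("binder_kd must be > 0")
        if self.binder_conc < 0:
            raise AggregationValidationError("binder_conc must be >= 0")
        if self.k2_factors is not None:
            for conc, f in self.k2_factors.items():
                if not 0 < f <= 1:
                    raise AggregationValidationError(
                        f"k2 factor at conc={conc} must be in (0, 1], got {f}"
                    )
        if self.ki is not None and not self.ki > 0:
            raise AggregationValidationError("ki must be > 0")

    def k2_factor(self, conc: float | None = None) -> float:
        """Secondary-nucleation scale factor at ``conc`` (default binder_conc)."""
        c = self.binder_conc if conc is None else conc
        if c == 0:
            return 1.0
        if self.ki is not None:
            return 1.0 / (1.0 + c / self.ki)
        if self.k2_factors:
            concs = np.array(sorted(self.k2_factors), dtype=float)
            facs = np.array([self.k2_factors[x] for x in concs], dtype=float)
            pos = concs > 0
            concs, facs = concs[pos], facs[pos]
            if concs.size == 0:
                return 1.0
            if c >= concs[-1]:
                return float(facs[-1])
            if c <= concs[0]:
                # anchor factor(0) == 1: linear in conc below the table
                return float(1.0 + (facs[0] - 1.0) * c / concs[0])
            return float(np.interp(math.log(c), np.log(concs), facs))
        return 1.0

    def effective_monomer(self, m_total: float) -> float:
        """Free monomer after sequestration at t = 0."""
        return free_monomer(
            EquilibriumSystem(l_tot=m_total, b_tot=self.binder_conc, kd=self.binder_kd)
        )


@dataclass(frozen=True)
class Trajectory:
    """Time course of the moment variables.

    ``m + M == m_total`` by mass conservation; ``M`` and ``P`` are
    nondecreasing for the unfragmented network.
    """

    t: np.ndarray
    m: np.ndarray
    fibril_mass: np.ndarray  # M(t)
    fibril_number: np.ndarray  # P(t)
    params: AggregationParameters

    def half_time(self) -> float:
        return half_time(self)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_s": self.t,
                "m_M": self.m,
                "M_M": self.fibril_mass,
                "P_M": self.fibril_number,
            }
        )


def simulate(params: AggregationParameters, t_grid) -> Trajectory:
    """Integrate the moment equations on ``t_grid`` (seconds, from 0).

    Uses LSODA with relative tolerance 1e-10; raises
    :class:`SimulationError` with a parameter echo if the solver fails.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.size < 2 or t[0] != 0 or np.any(np.diff(t) <= 0):
        raise AggregationValidationError("t_grid must be strictly increasing from 0")
    mtot = params.m_total

    def rhs(_t, y):
        p, big_m = y
        m = max(mtot - big_m, 0.0)
        dp = params.kn * m**params.nc + params.k2 * m**params.n2 * big_m
        dm = params.growth_ends * params.kplus * m * p
        return (dp, dm)

    sol = solve_ivp(
        rhs,
        (0.0, float(t[-1])),
        (params.p0, params.m0),
        method="LSODA",
        t_eval=t,
        rtol=1e-10,
        atol=(mtot * 1e-16, mtot * 1e-14),
    )
    if not sol.success:
        raise SimulationError(f"ODE solver failed ({sol.message}) for params={params}")
    big_m = np.clip(sol.y[1], 0.0, mtot)
    return Trajectory(
        t=t,
        m=mtot - big_m,
        fibril_mass=big_m,
        fibril_number=np.maximum(sol.y[0], 0.0),
        params=params,
    )


def _timescale(params: AggregationParameters) -> float:
    """Characteristic growth-rate scale: max of the two proliferation rates.

    kappa = sqrt(2 k+ k2 m^(n2+1)) controls secondary-nucleation-dominated
    growth; lambda = sqrt(2 k+ kn m^nc) controls the primary pathway.
    """
    m = params.m_total
    kappa = math.sqrt(2.0 * params.kplus * params.k2 * m ** (params.n2 + 1))
    lam = math.sqrt(2.0 * params.kplus * params.kn * m**params.nc)
    seeded = params.growth_ends * params.kplus * m * params.p0 / m if params.p0 else 0.0
    rate = max(kappa, lam, seeded)
    if rate == 0:
        raise AggregationValidationError(
            "no nucleation source: aggregation never starts (kn=k2=0, unseeded)"
        )
    return 1.0 / rate


def simulate_auto(params: AggregationParameters, n_points: int = 600) -> Trajectory:
    """Simulate on an automatically chosen grid long enough to plateau.

    The initial horizon is a multiple of the characteristic proliferation
    time ``1/max(kappa, lambda)``; it is doubled (up to 8x) until the fibril
    mass has flattened.
    """
    tau = _timescale(params)
    horizon = 30.0 * tau
    for _ in range(8):
        t = np.linspace(0.0, horizon, n_points)
        traj = simulate(params, t)
        if _plateau_reached(traj.fibril_mass, params.m_total):
            return traj
        horizon *= 2.0
    return traj


def _plateau_reached(big_m: np.ndarray, mtot: float) -> bool:
    if big_m[-1] < 0.5 * mtot:
        return False
    tail = big_m[-max(len(big_m) // 20, 2) :]
    return (tail[-1] - tail[0]) < 0.01 * big_m[-1]


def curve_half_time(t, y) -> float:
    """Time of the first crossing of half the plateau of a sigmoidal curve.

    The plateau is the final value; the curve must have flattened (last 5%
    of points changing by < 2% of the plateau), otherwise
    :class:`IncompleteCurveError` is raised.  The crossing is located by
    linear interpolation between the bracketing samples.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 3:
        raise IncompleteCurveError("need at least 3 points for a half-time")
    ntail = max(y.size // 10, 4)
    tail = y[-ntail:]
    plateau = float(np.mean(tail))
    if plateau <= 0:
        raise IncompleteCurveError("curve never rises above zero")
    # still-rising check on tail-segment means (robust to measurement noise)
    drift = float(np.mean(tail[ntail // 2 :]) - np.mean(tail[: ntail // 2]))
    if drift > 0.02 * plateau:
        raise IncompleteCurveError(
            "incomplete curve: no plateau within the sampled window"
        )
    target = 0.5 * plateau
    above = np.nonzero(y >= target)[0]
    if above.size == 0:
        raise IncompleteCurveError("curve never reaches half its plateau")
    i = int(above[0])
    if i == 0:
        return float(t[0])
    frac = (target - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def half_time(traj: Trajectory) -> float:
    """Aggregation half-time t1/2: 50% of the fibril-mass plateau."""
    return curve_half_time(traj.t, traj.fibril_mass)


def apply_inhibitor(
    params: AggregationParameters, inhib: InhibitorModel
) -> AggregationParameters:
    """Parameters of the effective uninhibited system under an inhibitor.

    Sequestration lowers ``m_total`` to the t = 0 free monomer; modulation
    scales ``k2``.  The returned parameters fed to :func:`simulate`
    reproduce :func:`simulate_with_inhibitor` exactly.
    """
    m_eff = inhib.effective_monomer(params.m_total)
    if not m_eff > 0:
        raise AggregationValidationError(
            "all monomer sequestered: effective monomer concentration is 0"
        )
    return replace(params, m_total=m_eff, k2=params.k2 * inhib.k2_factor())


def simulate_with_inhibitor(
    params: AggregationParameters, inhib: InhibitorModel, t_grid
) -> Trajectory:
    """Simulate aggregation in the presence of a monomer-binding inhibitor.

    The monomer-binder equilibrium is evaluated once at t = 0 and bound
    monomer is removed for the whole reaction (no re-equilibration during
    aggregation); secondary nucleation is scaled by the inhibitor's factor.
    """
    return simulate(apply_inhibitor(params, inhib), t_grid)


def half_time_scaling(
    params: AggregationParameters, m_grid, n_points: int = 400
) -> float:
    """Least-squares slope of log t1/2 versus log m_total.

    A diagnostic of the dominant pathway: secondary-nucleation-dominated
    kinetics with n2 = 2 give a slope near -1.5; purely primary-nucleated
    kinetics with nc = 2 give a shallower slope near -1.
    """
    m_grid = np.asarray(m_grid, dtype=float)
    if np.unique(m_grid).size < 4:
        raise AggregationValidationError("need >= 4 distinct monomer concentrations")
    if np.any(m_grid <= 0):
        raise AggregationValidationError("monomer concentrations must be > 0")
    halves = [
        half_time(simulate_auto(replace(params, m_total=float(m)), n_points))
        for m in m_grid
    ]
    slope = np.polyfit(np.log(m_grid), np.log(halves), 1)[0]
    return float(slope)
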