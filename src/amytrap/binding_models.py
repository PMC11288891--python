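"""1:1 binding models and nonlinear least-squares fits for BLI and MDS.

Three measurement modes share the same underlying 1:1 equilibrium
``L + B <-> LB`` with dissociation constant ``Kd = koff/kon``:

* **BLI kinetics** — sensor response follows ``dR/dt = kon*C*(Rmax-R) -
  koff*R`` for analyte concentration ``C``, giving mono-exponential
  association to ``Req = Rmax*C/(C+Kd)`` with observed rate
  ``kobs = kon*C + koff``, and exponential dissociation at ``koff``.
* **BLI steady state** — equilibrium responses follow the simple Langmuir
  isotherm ``R = Rmax*C/(C+Kd)`` (analyte in excess; no depletion).
* **MDS** — both species are comparably dilute, so the exact
  ligand-depletion quadratic is used: the complex concentration is the
  physical root of ``C^2 - (L+B+Kd)*C + L*B = 0``.

All concentrations are molar and times seconds throughout.  Fits use
trust-region least squares with multi-start over log-spaced Kd values;
standard errors come from the Jacobian at the optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "BindingParameters",
    "EquilibriumSystem",
    "MDSReadout",
    "FitResult",
    "complex_conc_quadratic",
    "free_monomer",
    "steady_state_response",
    "association_trace",
    "dissociation_trace",
    "fit_steady_state",
    "fit_kinetic_global",
    "fit_mds_quadratic",
]

_KD_CONSISTENCY_RTOL = 1e-9


class BindingValidationError(ValueError):
    """Invalid binding-model inputs."""


@dataclass(frozen=True)
class BindingParameters:
    """Rate and equilibrium constants of a 1:1 interaction.

    Any subset may be supplied; ``kd`` is filled in as ``koff/kon`` when both
    rates are given, and consistency is enforced when all three are set.
    Units: ``kon`` M^-1 s^-1, ``koff`` s^-1, ``kd`` M, ``rmax`` sensor units.
    """

    kon: float | None = None
    koff: float | None = None
    kd: float | None = None
    rmax: float | None = None

    def __post_init__(self) -> None:
        for name in ("kon", "koff", "kd", "rmax"):
            val = getattr(self, name)
            if val is not None and not val > 0:
                raise BindingValidationError(f"{name} must be strictly positive, got {val}")
        if self.kon is not None and self.koff is not None:
            implied = self.koff / self.kon
            if self.kd is None:
                object.__setattr__(self, "kd", implied)
            elif not math.isclose(self.kd, implied, rel_tol=_KD_CONSISTENCY_RTOL):
                raise BindingValidationError(
                    f"kd={self.kd!r} inconsistent with koff/kon={implied!r}"
                )


@dataclass(frozen=True)
class EquilibriumSystem:
    """Total concentrations for a depleting 1:1 equilibrium (molar)."""

    l_tot: float  # labeled / tracked species (e.g. monomer)
    b_tot: float  # binder
    kd: float

    def __post_init__(self) -> None:
        if self.l_tot < 0 or self.b_tot < 0:
            raise BindingValidationError(
                f"total concentrations must be >= 0 (l_tot={self.l_tot}, b_tot={self.b_tot})"
            )
        if not self.kd > 0:
            raise BindingValidationError(f"kd must be > 0, got {self.kd}")


@dataclass(frozen=True)
class MDSReadout:
    """Hydrodynamic-radius readout of a diffusional-sizing measurement."""

    rh_free: float  # nm
    rh_complex: float  # nm
    fraction_bound: float

    def __post_init__(self) -> None:
        if not 0 < self.rh_free <= self.rh_complex:
            raise BindingValidationError(
                f"need 0 < rh_free <= rh_complex, got {self.rh_free}, {self.rh_complex}"
            )
        if not 0 <= self.fraction_bound <= 1:
            raise BindingValidationError(
                f"fraction_bound must be in [0, 1], got {self.fraction_bound}"
            )

    @property
    def rh_observed(self) -> float:
        """Fraction-weighted mean radius."""
        return self.rh_free + self.fraction_bound * (self.rh_complex - self.rh_free)


def complex_conc_quadratic(sys: EquilibriumSystem) -> float:
    """Complex concentration from the exact ligand-depletion quadratic.

    Returns the physical root
    ``C = [(L+B+Kd) - sqrt((L+B+Kd)^2 - 4LB)] / 2`` evaluated in the
    numerically stable form ``2LB / (s + sqrt(s^2 - 4LB))``, which avoids
    catastrophic cancellation when ``Kd`` dominates.  ``0 <= C <= min(L, B)``.
    """
    a, b = sys.l_tot, sys.b_tot
    if a == 0.0 or b == 0.0:
        return 0.0
    s = a + b + sys.kd
    disc = s * s - 4.0 * a * b  # = (a-b)^2 + kd^2 + 2kd(a+b) >= 0
    return 2.0 * a * b / (s + math.sqrt(disc))


def free_monomer(sys: EquilibriumSystem) -> float:
    """Free (unbound) tracked-species concentration, ``L - C``, in [0, L]."""
    return max(sys.l_tot - complex_conc_quadratic(sys), 0.0)


def steady_state_response(conc, p: BindingParameters):
    """Langmuir equilibrium response ``Rmax * C / (C + Kd)``."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise BindingValidationError("analyte concentration must be >= 0")
    if p.rmax is None or p.kd is None:
        raise BindingValidationError("steady_state_response requires rmax and kd")
    return p.rmax * conc / (conc + p.kd)


def association_trace(t_grid, conc: float, p: BindingParameters) -> np.ndarray:
    """Association-phase response ``Req * (1 - exp(-(kon*C + koff) t))``."""
    t = _check_time_grid(t_grid)
    if conc < 0:
        raise BindingValidationError("analyte concentration must be >= 0")
    if p.kon is None or p.koff is None or p.rmax is None:
        raise BindingValidationError("association_trace requires kon, koff and rmax")
    req = p.rmax * conc / (conc + p.kd)
    kobs = p.kon * conc + p.koff
    return req * (1.0 - np.exp(-kobs * t))


def dissociation_trace(t_grid, r0: float, p: BindingParameters) -> np.ndarray:
    """Dissociation-phase response ``R0 * exp(-koff t)``."""
    t = _check_time_grid(t_grid)
    if p.koff is None:
        raise BindingValidationError("dissociation_trace requires koff")
    return r0 * np.exp(-p.koff * t)


def _check_time_grid(t_grid) -> np.ndarray:
    t = np.asarray(t_grid, dtype=float)
    if t.size and (t[0] < 0 or np.any(np.diff(t) < 0)):
        raise BindingValidationError("time grid must be nondecreasing from t >= 0")
    return t


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class FitResult:
    """Outcome of a nonlinear least-squares fit.

    ``params`` and ``stderr`` are keyed by parameter name; ``stderr`` entries
    are NaN when the Jacobian is singular.  ``warnings`` collects
    non-fatal diagnostics such as non-identifiability flags.
    """

    params: dict[str, float]
    stderr: dict[str, float]
    residual_norm: float
    converged: bool
    message: str
    n_obs: int
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.converged:
            raise FitConvergenceError(self.message)


class FitConvergenceError(RuntimeError):
    """The optimizer failed to converge; never returned silently."""


def _multistart_least_squares(residual_fn, starts, bounds):
    """Run least_squares from several starts; keep the best converged fit."""
    best = None
    messages = []
    for x0 in starts:
        try:
            sol = least_squares(residual_fn, x0, bounds=bounds, method="trf")
        except Exception as exc:  # pragma: no cover - numerical edge
            messages.append(str(exc))
            continue
        if not sol.success:
            messages.append(sol.message)
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitConvergenceError(
            "least-squares fit failed from all starts: " + "; ".join(messages)
        )
    return best


def _stderr_from_jacobian(sol, names: Sequence[str]) -> dict[str, float]:
    m, n = sol.jac.shape
    dof = max(m - n, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(n, np.nan)
    return dict(zip(names, se))


def _identifiability_warning(concs: np.ndarray, kd: float) -> list[str]:
    warns = []
    if np.all(concs >= 10.0 * kd):
        warns.append(
            "all concentrations >> fitted Kd: Kd poorly identified (saturated design)"
        )
    elif np.all(concs <= 0.1 * kd):
        warns.append(
            "all concentrations << fitted Kd: Kd poorly identified (linear regime)"
        )
    return warns


def _kd_starts(lo: float, hi: float, n: int = 5) -> np.ndarray:
    return np.logspace(math.log10(lo), math.log10(hi), n)


def fit_steady_state(data: pd.DataFrame) -> FitResult:
    """Fit ``Rmax`` and ``Kd`` of the Langmuir isotherm to titration data.

    ``data`` is long-format with columns ``conc_M`` and ``response``
    (``replicate`` optional).  Requires >= 4 distinct concentrations.
    """
    conc, resp = _require_titration(data, "response")
    rmax0 = float(resp.max()) * 1.2 + 1e-12

    def residuals(theta):
        log_kd, rmax = theta
        return rmax * conc / (conc + 10.0**log_kd) - resp

    starts = [
        (math.log10(kd), rmax0)
        for kd in _kd_starts(conc[conc > 0].min() / 100.0, conc.max() * 100.0)
    ]
    sol = _multistart_least_squares(
        residuals, starts, bounds=([-15.0, 0.0], [0.0, np.inf])
    )
    kd = 10.0 ** sol.x[0]
    se = _stderr_from_jacobian(sol, ["log10_kd", "rmax"])
    return FitResult(
        params={"kd": kd, "rmax": sol.x[1]},
        stderr={"kd": kd * math.log(10.0) * se["log10_kd"], "rmax": se["rmax"]},
        residual_norm=math.sqrt(2.0 * sol.cost),
        converged=True,
        message=sol.message,
        n_obs=conc.size,
        warnings=_identifiability_warning(conc, kd),
    )


def fit_kinetic_global(data: pd.DataFrame) -> FitResult:
    """Global 1:1 kinetic fit of BLI association/dissociation traces.

    ``data`` is long-format with columns ``time_s``, ``conc_M``, ``phase``
    (``association`` | ``dissociation``; dissociation times start at 0 at
    the phase boundary) and ``response`` (``replicate`` optional).  A single
    set of ``kon``, ``koff``, ``rmax`` is shared across all analyte
    concentrations; each trace's dissociation starts from the model's
    association endpoint.  Reported ``kd = koff/kon``.
    """
    required = {"time_s", "conc_M", "phase", "response"}
    missing = required - set(data.columns)
    if missing:
        raise BindingValidationError(f"kinetic data missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(data["response"].to_numpy(dtype=float))):
        raise BindingValidationError("non-finite responses in kinetic data")
    concs = np.sort(data["conc_M"].unique())
    if concs.size < 4:
        raise BindingValidationError(
            f"need >= 4 distinct concentrations, got {concs.size}"
        )
    if "replicate" not in data.columns:
        data = data.assign(replicate=0)

    traces = []
    for (conc, rep), grp in data.groupby(["conc_M", "replicate"]):
        assoc = grp[grp["phase"] == "association"]
        dissoc = grp[grp["phase"] == "dissociation"]
        ta = assoc["time_s"].to_numpy(dtype=float)
        traces.append(
            (
                float(conc),
                ta,
                assoc["response"].to_numpy(dtype=float),
                float(ta.max()) if ta.size else 0.0,
                dissoc["time_s"].to_numpy(dtype=float),
                dissoc["response"].to_numpy(dtype=float),
            )
        )
    rmax0 = float(data["response"].max()) * 1.2 + 1e-12

    def residuals(theta):
        kon, koff, rmax = 10.0 ** theta[0], 10.0 ** theta[1], theta[2]
        p = BindingParameters(kon=kon, koff=koff, rmax=rmax)
        out = []
        for conc, ta, ra, ta_end, td, rd in traces:
            if ta.size:
                out.append(association_trace(ta, conc, p) - ra)
            if td.size:
                r0 = float(association_trace(np.array([ta_end]), conc, p)[0])
                out.append(dissociation_trace(td, r0, p) - rd)
        return np.concatenate(out)

    kd_grid = _kd_starts(concs[concs > 0].min() / 100.0, concs.max() * 100.0)
    starts = [(4.0, 4.0 + math.log10(kd), rmax0) for kd in kd_grid]
    sol = _multistart_least_squares(
        residuals, starts, bounds=([-2.0, -10.0, 0.0], [9.0, 3.0, np.inf])
    )
    kon, koff, rmax = 10.0 ** sol.x[0], 10.0 ** sol.x[1], sol.x[2]
    se = _stderr_from_jacobian(sol, ["log10_kon", "log10_koff", "rmax"])
    ln10 = math.log(10.0)
    return FitResult(
        params={"kon": kon, "koff": koff, "kd": koff / kon, "rmax": rmax},
        stderr={
            "kon": kon * ln10 * se["log10_kon"],
            "koff": koff * ln10 * se["log10_koff"],
            "rmax": se["rmax"],
        },
        residual_norm=math.sqrt(2.0 * sol.cost),
        converged=True,
        message=sol.message,
        n_obs=int(data.shape[0]),
        warnings=_identifiability_warning(concs, koff / kon),
    )


def fit_mds_quadratic(
    data: pd.DataFrame,
    l_tot: float,
    fit_endpoints: bool = True,
) -> FitResult:
    """Fit ``Kd`` with the exact ligand-depletion quadratic to MDS titrations.

    ``data`` is long-format with column ``conc_M`` (total binder) and either
    ``fraction_bound`` or ``radius_nm``; ``l_tot`` is the labeled-species
    concentration (molar).  With a radius readout the two radius endpoints
    are estimated jointly by default (``fit_endpoints=True``) or fixed to
    the extreme observed values.
    """
    if not l_tot > 0:
        raise BindingValidationError("l_tot must be > 0")
    value_col = "radius_nm" if "radius_nm" in data.columns else "fraction_bound"
    conc, obs = _require_titration(data, value_col)

    def frac_bound(log_kd):
        kd = 10.0**log_kd
        s = l_tot + conc + kd
        c = 2.0 * l_tot * conc / (s + np.sqrt(s * s - 4.0 * l_tot * conc))
        return c / l_tot

    lo = max(min(conc[conc > 0].min(), l_tot) / 100.0, 1e-14)
    hi = conc.max() * 100.0
    if value_col == "fraction_bound":

        def residuals(theta):
            return frac_bound(theta[0]) - obs

        starts = [(math.log10(kd),) for kd in _kd_starts(lo, hi)]
        sol = _multistart_least_squares(residuals, starts, bounds=([-15.0], [0.0]))
        kd = 10.0 ** sol.x[0]
        se = _stderr_from_jacobian(sol, ["log10_kd"])
        params = {"kd": kd}
        stderr = {"kd": kd * math.log(10.0) * se["log10_kd"]}
    else:
        r_lo0, r_hi0 = float(obs.min()), float(obs.max())
        if fit_endpoints:

            def residuals(theta):
                log_kd, r_free, r_cplx = theta
                return r_free + frac_bound(log_kd) * (r_cplx - r_free) - obs

            starts = [
                (math.log10(kd), r_lo0, r_hi0 + 1e-9) for kd in _kd_starts(lo, hi)
            ]
            sol = _multistart_least_squares(
                residuals, starts, bounds=([-15.0, 0.0, 0.0], [0.0, np.inf, np.inf])
            )
            kd = 10.0 ** sol.x[0]
            se = _stderr_from_jacobian(sol, ["log10_kd", "rh_free", "rh_complex"])
            params = {"kd": kd, "rh_free": sol.x[1], "rh_complex": sol.x[2]}
            stderr = {
                "kd": kd * math.log(10.0) * se["log10_kd"],
                "rh_free": se["rh_free"],
                "rh_complex": se["rh_complex"],
            }
        else:

            def residuals(theta):
                return r_lo0 + frac_bound(theta[0]) * (r_hi0 - r_lo0) - obs

            starts = [(math.log10(kd),) for kd in _kd_starts(lo, hi)]
            sol = _multistart_least_squares(residuals, starts, bounds=([-15.0], [0.0]))
            kd = 10.0 ** sol.x[0]
            se = _stderr_from_jacobian(sol, ["log10_kd"])
            params = {"kd": kd, "rh_free": r_lo0, "rh_complex": r_hi0}
            stderr = {"kd": kd * math.log(10.0) * se["log10_kd"]}
    return FitResult(
        params=params,
        stderr=stderr,
        residual_norm=math.sqrt(2.0 * sol.cost),
        converged=True,
        message=sol.message,
        n_obs=conc.size,
        warnings=_identifiability_warning(conc, params["kd"]),
    )


def _require_titration(data: pd.DataFrame, value_col: str):
    for col in ("conc_M", value_col):
        if col not in data.columns:
            raise BindingValidationError(f"titration data missing column {col!r}")
    conc = data["conc_M"].to_numpy(dtype=float)
    obs = data[value_col].to_numpy(dtype=float)
    if not np.all(np.isfinite(obs)):
        raise BindingValidationError(f"non-finite values in column {value_col!r}")
    n_distinct = np.unique(conc).size
    if n_distinct < 4:
        raise BindingValidationError(
            f"need >= 4 distinct concentrations, got {n_distinct}"
        )
    return conc, obs
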