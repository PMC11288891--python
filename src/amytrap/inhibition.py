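"""Inference pipeline over ThT aggregation datasets.

The analysis mirrors the experimental logic for dissecting how a
monomer-binding design inhibits Aβ42 fibril formation:

1. normalize raw ThT fluorescence to fraction aggregated
   (:func:`normalize_tht`);
2. fit the uninhibited moment model to the binder-free traces to obtain the
   identifiable rate products ``kn*kplus`` and ``k2*kplus``
   (:func:`fit_uninhibited`);
3. predict inhibited curves under monomer sequestration alone, using the
   independently measured monomer affinity, and quantify how far that falls
   short of the data (:func:`predict_sequestration_only`);
4. fit a secondary-nucleation suppression factor per binder concentration
   on top of sequestration (:func:`fit_secondary_modulation`);
5. summarize potency as the binder concentration that increases the
   aggregation half-time by a fixed fraction, 50% by default
   (:func:`potency_concentration`).

Because normalized curves are invariant to rescaling ``P -> kplus*P``, only
the products ``kn*kplus`` and ``k2*kplus`` are identifiable from ThT data;
fits are parametrized accordingly and an internal elongation constant is
used only to factor the products for the simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from amytrap.aggregation import (
    AggregationParameters,
    IncompleteCurveError,
    InhibitorModel,
    Trajectory,
    apply_inhibitor,
    curve_half_time,
    half_time,
    simulate,
    simulate_auto,
)
from amytrap.binding_models import FitConvergenceError

__all__ = [
    "Trace",
    "ThTDataset",
    "UninhibitedFit",
    "InhibitionFitResult",
    "normalize_tht",
    "fit_uninhibited",
    "predict_sequestration_only",
    "fit_secondary_modulation",
    "potency_concentration",
]

# Internal elongation constant used to factor the identifiable rate products
# (kn*kplus, k2*kplus) into simulator parameters; normalized curves do not
# depend on its value.
_KPLUS_INTERNAL = 3.0e6

#: Traces where more than this fraction of monomer is predicted bound are
#: excluded from modulation fitting (the sequestration-dominated regime where
#: the model is known to perform poorly).
BOUND_FRACTION_EXCLUDE = 0.9


class ThTValidationError(ValueError):
    pass


@dataclass(frozen=True)
class Trace:
    """One ThT time course: times (s) and fluorescence (a.u. or normalized)."""

    t: np.ndarray
    f: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        f = np.asarray(self.f, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "f", f)
        if t.shape != f.shape:
            raise ThTValidationError("time and fluorescence arrays differ in length")
        if np.any(np.diff(t) < 0):
            raise ThTValidationError("times must be nondecreasing within a trace")


@dataclass
class ThTDataset:
    """Tidy collection of ThT traces keyed by (binder_conc, replicate).

    ``monomer_conc`` is the total monomer (molar).  ``normalized`` marks
    fluorescence already mapped to fraction aggregated.  ``flags`` carries
    per-trace annotations set by the pipeline (``no_aggregation``,
    ``borrowed_plateau``, ``excluded_bound_fraction``).
    """

    traces: dict[tuple[float, int], Trace]
    monomer_conc: float
    binder_name: str = ""
    binder_kd: float | None = None
    normalized: bool = False
    flags: dict[tuple[float, int], list[str]] = field(default_factory=dict)
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        if not any(conc == 0.0 for conc, _rep in self.traces):
            raise ThTValidationError(
                "dataset must contain at least one uninhibited (binder_conc=0) trace"
            )
        if not self.monomer_conc > 0:
            raise ThTValidationError("monomer_conc must be > 0")

    def binder_concs(self) -> list[float]:
        return sorted({conc for conc, _ in self.traces})

    def traces_at(self, conc: float) -> dict[int, Trace]:
        return {rep: tr for (c, rep), tr in self.traces.items() if c == conc}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (conc, rep), tr in sorted(self.traces.items()):
            rows.append(
                pd.DataFrame(
                    {"t_s": tr.t, "F": tr.f, "binder_conc_M": conc, "replicate": rep}
                )
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, monomer_conc: float, **kwargs
    ) -> "ThTDataset":
        required = {"t_s", "F", "binder_conc_M", "replicate"}
        missing = required - set(frame.columns)
        if missing:
            raise ThTValidationError(f"ThT table missing columns: {sorted(missing)}")
        traces = {}
        for (conc, rep), grp in frame.groupby(["binder_conc_M", "replicate"]):
            grp = grp.sort_values("t_s")
            traces[(float(conc), int(rep))] = Trace(
                grp["t_s"].to_numpy(), grp["F"].to_numpy()
            )
        return cls(traces=traces, monomer_conc=monomer_conc, **kwargs)


@dataclass(frozen=True)
class UninhibitedFit:
    """Identifiable rate products fitted to binder-free traces."""

    kn_kplus: float  # kn * k+  (M^-nc s^-2 units for nc=2: M^-1 s^-2 * ...)
    k2_kplus: float  # k2 * k+
    nc: float
    n2: float
    monomer_conc: float
    residual_norm: float
    half_time_s: float

    def params(self, m_total: float | None = None) -> AggregationParameters:
        """Simulator parameters reproducing the fitted normalized kinetics."""
        return AggregationParameters(
            kn=self.kn_kplus / _KPLUS_INTERNAL,
            kplus=_KPLUS_INTERNAL,
            k2=self.k2_kplus / _KPLUS_INTERNAL,
            m_total=self.monomer_conc if m_total is None else m_total,
            nc=self.nc,
            n2=self.n2,
        )


@dataclass
class InhibitionFitResult:
    """Full output of the sequential inhibition analysis."""

    uninhibited: UninhibitedFit
    binder_kd: float
    k2_factors: dict[float, float]
    ki: float | None
    residual_norms: dict[float, float]
    excluded_concs: list[float]
    half_times: dict[float, float]
    potency_conc: float | None = None

    def inhibitor_model(self, conc: float) -> InhibitorModel:
        if self.ki is not None:
            return InhibitorModel(binder_kd=self.binder_kd, binder_conc=conc, ki=self.ki)
        return InhibitorModel(
            binder_kd=self.binder_kd, binder_conc=conc, k2_factors=self.k2_factors
        )


# ---------------------------------------------------------------------------
# Normalization


def normalize_tht(dataset: ThTDataset) -> ThTDataset:
    """Map raw fluorescence to fraction aggregated, trace by trace.

    The baseline is the mean of the first 5 points; the plateau is the mean
    of the last 5 points when the trace has flattened, otherwise the mean
    uninhibited plateau amplitude is borrowed (flag ``borrowed_plateau``).
    Traces with no detectable rise are flagged ``no_aggregation`` and
    returned as baseline-subtracted zeros.  Already-normalized datasets are
    returned unchanged (idempotence).
    """
    if dataset.normalized:
        return dataset
    for key, tr in dataset.traces.items():
        if tr.t.size < 10:
            raise ThTValidationError(
                f"trace {key} has {tr.t.size} points; >= 10 required to normalize"
            )

    def amplitude(tr: Trace) -> tuple[float, float, bool]:
        baseline = float(np.mean(tr.f[:5]))
        plateau = float(np.mean(tr.f[-5:]))
        ntail = max(tr.f.size // 10, 10)
        tail = tr.f[-ntail:]
        rise = plateau - baseline
        # flat when tail-segment means stop drifting (robust to noise)
        drift = float(np.mean(tail[ntail // 2 :]) - np.mean(tail[: ntail // 2]))
        flat = rise > 0 and abs(drift) < 0.05 * rise
        return baseline, rise, flat

    uninhibited_amps = [
        amplitude(tr)[1] for tr in dataset.traces_at(0.0).values() if amplitude(tr)[2]
    ]
    borrowed = float(np.mean(uninhibited_amps)) if uninhibited_amps else None

    out_traces: dict[tuple[float, int], Trace] = {}
    flags: dict[tuple[float, int], list[str]] = {k: list(v) for k, v in dataset.flags.items()}
    for key, tr in dataset.traces.items():
        baseline, rise, flat = amplitude(tr)
        fl = flags.setdefault(key, [])
        span = float(tr.f.max() - baseline)
        if borrowed is not None and span < 0.05 * borrowed:
            fl.append("no_aggregation")
            out_traces[key] = Trace(tr.t, np.zeros_like(tr.f))
            continue
        if flat:
            amp = rise
        else:
            if borrowed is None:
                raise ThTValidationError(
                    f"trace {key} never plateaus and no uninhibited plateau is available"
                )
            amp = borrowed
            fl.append("borrowed_plateau")
        out_traces[key] = Trace(tr.t, (tr.f - baseline) / amp)
    return ThTDataset(
        traces=out_traces,
        monomer_conc=dataset.monomer_conc,
        binder_name=dataset.binder_name,
        binder_kd=dataset.binder_kd,
        normalized=True,
        flags=flags,
        ground_truth=dataset.ground_truth,
    )


# ---------------------------------------------------------------------------
# Model evaluation helpers


def _normalized_model_curve(
    params: AggregationParameters,
    t: np.ndarray,
    self_normalized: bool,
    ref_m_total: float | None = None,
) -> np.ndarray:
    """Model fraction-aggregated curve on the data grid.

    Self-normalized traces plateau at 1 by construction, so the model curve
    is M(t)/M(end).  Borrowed-plateau traces were scaled by the *uninhibited*
    amplitude, which in signal units corresponds to the full monomer pool
    ``ref_m_total`` (not the sequestration-reduced ``params.m_total``), so
    the model curve is M(t)/ref_m_total.
    """
    grid = t if t[0] == 0 else np.concatenate(([0.0], t))
    traj = simulate(params, grid)
    big_m = traj.fibril_mass[-t.size :]
    if self_normalized:
        plateau = traj.fibril_mass[-1]
        return big_m / plateau if plateau > 0 else np.zeros_like(big_m)
    return big_m / (ref_m_total if ref_m_total is not None else params.m_total)


def fit_uninhibited(dataset: ThTDataset) -> UninhibitedFit:
    """Fit the rate products (kn*k+, k2*k+) to the binder-free traces.

    The dataset is normalized first if needed.  The fit is least squares in
    log10 of the two products over all uninhibited traces jointly, with
    starts derived from the observed half-time.
    """
    ds = normalize_tht(dataset)
    zero = ds.traces_at(0.0)
    if not zero:
        raise ThTValidationError("no uninhibited traces to fit")
    m = ds.monomer_conc
    nc, n2 = 2.0, 2.0

    # Initial guesses from the observed half-time: kappa ~ 3/t_half for
    # secondary-dominated curves, lambda = kappa/20 as a weak primary pathway.
    t_half0 = np.median(
        [curve_half_time(tr.t, tr.f) for tr in zero.values()]
    )
    kappa0 = 3.0 / t_half0
    b0 = kappa0**2 / (2.0 * m ** (n2 + 1))  # k2*k+
    a0 = (kappa0 / 20.0) ** 2 / (2.0 * m**nc)  # kn*k+

    def residuals(theta):
        a, b = 10.0 ** theta[0], 10.0 ** theta[1]
        params = AggregationParameters(
            kn=a / _KPLUS_INTERNAL,
            kplus=_KPLUS_INTERNAL,
            k2=b / _KPLUS_INTERNAL,
            m_total=m,
            nc=nc,
            n2=n2,
        )
        out = []
        for tr in zero.values():
            model = _normalized_model_curve(params, tr.t, self_normalized=True)
            out.append(model - tr.f)
        return np.concatenate(out)

    best = None
    for da in (-1.0, 0.0, 1.0):
        x0 = (math.log10(a0) + da, math.log10(b0))
        sol = least_squares(residuals, x0, method="trf", diff_step=1e-4)
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitConvergenceError("uninhibited aggregation fit failed to converge")
    a, b = 10.0 ** best.x[0], 10.0 ** best.x[1]
    fit = UninhibitedFit(
        kn_kplus=a,
        k2_kplus=b,
        nc=nc,
        n2=n2,
        monomer_conc=m,
        residual_norm=math.sqrt(2.0 * best.cost),
        half_time_s=float(t_half0),
    )
    return fit


def predict_sequestration_only(
    fit: UninhibitedFit,
    binder_kd: float | None,
    binder_concs,
    dataset: ThTDataset | None = None,
) -> dict[float, dict]:
    """Predicted curves if the binder only removed monomer from the reaction.

    For each binder concentration, simulates the fitted model at the
    sequestration-reduced monomer concentration with the secondary
    nucleation rate untouched.  When ``dataset`` is given, per-concentration
    residuals against the (normalized) data quantify how insufficient
    sequestration alone is.

    Returns ``{conc: {"t", "curve", "m_eff", "residual_norm"}}``; curves are
    on the fraction-of-total-monomer scale.
    """
    if binder_kd is None:
        raise ThTValidationError(
            "binder_kd is required: measure it first (e.g. fit_mds_quadratic)"
        )
    ds = normalize_tht(dataset) if dataset is not None else None
    out: dict[float, dict] = {}
    for conc in binder_concs:
        inhib = InhibitorModel(binder_kd=binder_kd, binder_conc=float(conc))
        params = apply_inhibitor(fit.params(), inhib)
        if ds is not None and ds.traces_at(conc):
            res = []
            t_ref = None
            curve_ref = None
            for key, tr in sorted(ds.traces.items()):
                if key[0] != conc:
                    continue
                self_norm = "borrowed_plateau" not in ds.flags.get(key, [])
                model = _normalized_model_curve(
                    params, tr.t, self_normalized=self_norm,
                    ref_m_total=fit.monomer_conc,
                )
                res.append(model - tr.f)
                t_ref, curve_ref = tr.t, model
            out[conc] = {
                "t": t_ref,
                "curve": curve_ref,
                "m_eff": params.m_total,
                "residual_norm": float(np.sqrt(np.sum(np.concatenate(res) ** 2))),
            }
        else:
            traj = simulate_auto(params)
            out[conc] = {
                "t": traj.t,
                "curve": traj.fibril_mass / fit.monomer_conc,
                "m_eff": params.m_total,
                "residual_norm": float("nan"),
            }
    return out


def fit_secondary_modulation(
    dataset: ThTDataset,
    fit: UninhibitedFit,
    binder_kd: float | None = None,
    parametric: bool = False,
) -> InhibitionFitResult:
    """Fit secondary-nucleation suppression factors on top of sequestration.

    Holding the uninhibited rate products and the sequestration coupling
    fixed, one factor in (0, 1] is fitted per binder concentration (default)
    or a single ``K_I`` of the parametric form ``1/(1+[I]/K_I)``
    (``parametric=True``).  Traces where more than 90% of the monomer is
    predicted bound are excluded from fitting and flagged.
    """
    ds = normalize_tht(dataset)
    kd = binder_kd if binder_kd is not None else ds.binder_kd
    if kd is None:
        raise ThTValidationError("binder_kd required (argument or dataset metadata)")
    inhibited_concs = [c for c in ds.binder_concs() if c > 0]
    if not inhibited_concs:
        raise ThTValidationError("no inhibited traces: nothing to fit")

    base = fit.params()
    excluded: list[float] = []
    usable: list[float] = []
    for conc in inhibited_concs:
        inhib = InhibitorModel(binder_kd=kd, binder_conc=conc)
        bound_frac = 1.0 - inhib.effective_monomer(base.m_total) / base.m_total
        if bound_frac > BOUND_FRACTION_EXCLUDE:
            excluded.append(conc)
            for key in ds.traces:
                if key[0] == conc:
                    ds.flags.setdefault(key, []).append("excluded_bound_fraction")
        else:
            usable.append(conc)

    def conc_residuals(conc: float, factor: float) -> np.ndarray:
        inhib = InhibitorModel(
            binder_kd=kd, binder_conc=conc, k2_factors={conc: factor}
        )
        params = apply_inhibitor(base, inhib)
        res = []
        for key, tr in sorted(ds.traces.items()):
            if key[0] != conc or "no_aggregation" in ds.flags.get(key, []):
                continue
            self_norm = "borrowed_plateau" not in ds.flags.get(key, [])
            model = _normalized_model_curve(
                params, tr.t, self_normalized=self_norm, ref_m_total=base.m_total
            )
            res.append(model - tr.f)
        return np.concatenate(res) if res else np.zeros(0)

    factors: dict[float, float] = {}
    residual_norms: dict[float, float] = {}
    ki = None
    if parametric:

        def residuals(theta):
            log_ki = theta[0]
            out = []
            for conc in usable:
                factor = 1.0 / (1.0 + conc / 10.0**log_ki)
                out.append(conc_residuals(conc, factor))
            return np.concatenate(out)

        best = None
        for log_ki0 in np.linspace(-8.0, -4.0, 5):
            sol = least_squares(
                residuals, (log_ki0,), bounds=([-12.0], [0.0]), method="trf",
                diff_step=1e-3,
            )
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise FitConvergenceError("parametric modulation fit failed")
        ki = 10.0 ** best.x[0]
        for conc in usable:
            f = 1.0 / (1.0 + conc / ki)
            factors[conc] = f
            residual_norms[conc] = float(np.linalg.norm(conc_residuals(conc, f)))
    else:
        for conc in usable:

            def residuals(theta, _c=conc):
                return conc_residuals(_c, float(theta[0]))

            best = None
            for f0 in (0.05, 0.3, 0.9):
                sol = least_squares(
                    residuals, (f0,), bounds=([1e-6], [1.0]), method="trf",
                    diff_step=1e-3,
                )
                if sol.success and (best is None or sol.cost < best.cost):
                    best = sol
            if best is None:
                raise FitConvergenceError(
                    f"modulation fit failed at binder_conc={conc}"
                )
            factors[conc] = float(best.x[0])
            residual_norms[conc] = math.sqrt(2.0 * best.cost)

    half_times: dict[float, float] = {}
    for conc in [0.0] + usable:
        inhib = InhibitorModel(
            binder_kd=kd,
            binder_conc=conc,
            k2_factors=factors if factors else None,
            ki=ki,
        )
        traj = simulate_auto(apply_inhibitor(base, inhib))
        half_times[conc] = half_time(traj)

    return InhibitionFitResult(
        uninhibited=fit,
        binder_kd=kd,
        k2_factors=factors,
        ki=ki,
        residual_norms=residual_norms,
        excluded_concs=excluded,
        half_times=half_times,
    )


def potency_concentration(
    fit: UninhibitedFit,
    binder_kd: float,
    modulation: Callable[[float], float] | Mapping[float, float] | None = None,
    increase: float = 0.5,
    conc_bounds: tuple[float, float] = (1e-12, 1e-3),
) -> float | None:
    """Binder concentration raising the aggregation half-time by ``increase``.

    Solves ``t_half([I]) / t_half(0) = 1 + increase`` by bisection on
    log10 [I] within ``conc_bounds``.  ``modulation`` maps binder
    concentration to the secondary-nucleation factor (callable, factor
    table, or None for sequestration-only).  Returns the concentration in
    molar, or ``None`` when the target slowdown is not reached within the
    bounds ("not reached").
    """
    if increase < 0:
        raise ThTValidationError("increase must be >= 0")
    if increase == 0:
        return 0.0
    base = fit.params()
    t0 = half_time(simulate_auto(base))

    def factor_at(conc: float) -> float:
        if modulation is None:
            return 1.0
        if callable(modulation):
            return float(modulation(conc))
        return InhibitorModel(
            binder_kd=binder_kd, binder_conc=conc, k2_factors=modulation
        ).k2_factor()

    def ratio_excess(log_c: float) -> float:
        conc = 10.0**log_c
        inhib = InhibitorModel(
            binder_kd=binder_kd, binder_conc=conc, k2_factors={conc: factor_at(conc)}
        )
        traj = simulate_auto(apply_inhibitor(base, inhib))
        return half_time(traj) / t0 - (1.0 + increase)

    lo, hi = math.log10(conc_bounds[0]), math.log10(conc_bounds[1])
    g_lo, g_hi = ratio_excess(lo), ratio_excess(hi)
    if g_lo > 0:
        return conc_bounds[0]
    if g_hi < 0:
        return None  # not reached within bounds
    log_c = brentq(ratio_excess, lo, hi, xtol=2e-3)
    return 10.0**log_c
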