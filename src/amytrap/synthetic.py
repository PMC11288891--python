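"""Synthetic ThT, BLI and MDS datasets with known ground truth.

Every generator draws from the forward models in
:mod:`amytrap.aggregation` and :mod:`amytrap.binding_models`, adds a simple
noise model, and bundles the generating parameters with the output so that
recovery tests are self-describing.  Defaults mirror the assay protocol the
analysis is built for: ThT read every 165 s at 2 µM monomer with three
replicates per condition; BLI titrations at a handful of analyte
concentrations around Kd; MDS titrations in triplicate.

Noise conventions (recorded in each dataset's ground truth): additive
Gaussian for ThT (sigma expressed as a fraction of the plateau amplitude,
default 0.02) and BLI (fraction of Rmax, default 0.01); additive Gaussian
on the 0-1 fraction-bound scale for MDS (default 0.03).

A single top-level seed drives everything; per-trace generators use
substreams spawned from it, so adding a condition does not perturb the
noise of existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from amytrap.aggregation import (
    AggregationParameters,
    InhibitorModel,
    apply_inhibitor,
    simulate,
    simulate_auto,
)
from amytrap.binding_models import (
    BindingParameters,
    EquilibriumSystem,
    association_trace,
    complex_conc_quadratic,
    dissociation_trace,
)
from amytrap.inhibition import ThTDataset, Trace
from amytrap.sequence_matching import TargetProtein

__all__ = [
    "SyntheticDataset",
    "default_aggregation_parameters",
    "gen_tht_dataset",
    "gen_bli_dataset",
    "gen_mds_dataset",
    "gen_scrambled_targets",
]


class SynthConfigError(ValueError):
    pass


@dataclass
class SyntheticDataset:
    """A generated table plus the ground truth that produced it."""

    data: pd.DataFrame
    truth: dict


def default_aggregation_parameters(m_total: float = 2e-6) -> AggregationParameters:
    """Order-of-magnitude Aβ42-like rate constants at 2 µM monomer.

    kn = 3e-4 M^-1 s^-1, k+ = 3e6 M^-1 s^-1, k2 = 1e4 M^-2 s^-1 with
    nc = n2 = 2 give secondary-nucleation-dominated sigmoids with half-times
    on the hour scale at micromolar monomer, the regime the analysis is
    designed for.  These are generator conventions, not fitted constants.
    """
    return AggregationParameters(
        kn=3e-4, kplus=3e6, k2=1e4, m_total=m_total, nc=2.0, n2=2.0
    )


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def gen_tht_dataset(
    seed: int,
    params: AggregationParameters | None = None,
    binder_kd: float = 83e-9,
    binder_concs: tuple[float, ...] = (0.0, 0.5e-6, 1e-6, 2e-6),
    k2_factors: dict[float, float] | None = None,
    replicates: int = 3,
    dt: float = 165.0,
    duration: float | None = None,
    noise_sigma: float = 0.02,
    signal_scale: float = 100.0,
    baseline: float = 10.0,
) -> ThTDataset:
    """Generate a ThT inhibition dataset from the aggregation model.

    Traces are ``a*M(t) + b + N(0, sigma)`` sampled every ``dt`` seconds
    (165 s by default), with ``a = signal_scale / m_total`` so the
    uninhibited plateau sits at ``signal_scale`` a.u. and ``sigma`` is
    ``noise_sigma`` of that amplitude.  ``k2_factors`` maps each binder
    concentration to its secondary-nucleation factor (default 1, i.e.
    sequestration-only truth).  The duration defaults to 12x the uninhibited
    half-time — plate runs monitor far beyond the control half-time — so
    moderately inhibited conditions complete while strongly inhibited ones
    may not plateau, as in a real plate run.
    """
    if params is None:
        params = default_aggregation_parameters()
    if noise_sigma < 0:
        raise SynthConfigError("noise_sigma must be >= 0")
    if not binder_concs or 0.0 not in binder_concs:
        raise SynthConfigError("binder_concs must be nonempty and include 0")
    k2_factors = dict(k2_factors or {})
    for conc in binder_concs:
        k2_factors.setdefault(conc, 1.0)

    if duration is None:
        from amytrap.aggregation import half_time

        duration = 12.0 * half_time(simulate_auto(params))
    n_pts = max(int(duration // dt) + 1, 10)
    t = np.arange(n_pts) * dt

    a = signal_scale / params.m_total
    sigma = noise_sigma * signal_scale
    rngs = iter(_substreams(seed, len(binder_concs) * replicates))
    traces: dict[tuple[float, int], Trace] = {}
    for conc in binder_concs:
        inhib = InhibitorModel(
            binder_kd=binder_kd, binder_conc=conc, k2_factors={conc: k2_factors[conc]}
        )
        eff = apply_inhibitor(params, inhib)
        grid = t if t[0] == 0 else np.concatenate(([0.0], t))
        traj = simulate(eff, grid)
        signal = a * traj.fibril_mass[-t.size :] + baseline
        for rep in range(replicates):
            rng = next(rngs)
            noisy = signal + rng.normal(0.0, sigma, size=t.size) if sigma > 0 else signal
            traces[(conc, rep)] = Trace(t.copy(), noisy)

    truth = {
        "assay": "tht",
        "seed": seed,
        "params": params,
        "binder_kd": binder_kd,
        "k2_factors": k2_factors,
        "signal_a": a,
        "signal_b": baseline,
        "noise_sigma_au": sigma,
        "dt_s": dt,
    }
    return ThTDataset(
        traces=traces,
        monomer_conc=params.m_total,
        binder_kd=binder_kd,
        ground_truth=truth,
    )


def gen_bli_dataset(
    seed: int,
    p: BindingParameters | None = None,
    conc_multiples: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0),
    t_assoc: float = 600.0,
    t_dissoc: float = 600.0,
    dt: float = 2.0,
    noise_sigma: float = 0.01,
    drift_per_s: float = 0.0,
) -> SyntheticDataset:
    """Generate 1:1 BLI association/dissociation traces with baseline noise.

    Analyte concentrations are multiples of Kd (default 0.25-4x).
    ``noise_sigma`` is a fraction of Rmax; ``drift_per_s`` adds an optional
    linear baseline drift in response units per second.
    """
    if p is None:
        p = BindingParameters(kon=1e4, koff=1e-3, rmax=1.0)
    if p.kon is None or p.koff is None or p.rmax is None:
        raise SynthConfigError("BLI generation needs kon, koff and rmax")
    if noise_sigma < 0:
        raise SynthConfigError("noise_sigma must be >= 0")
    ta = np.arange(0.0, t_assoc + dt / 2, dt)
    td = np.arange(0.0, t_dissoc + dt / 2, dt)
    sigma = noise_sigma * p.rmax
    rows = []
    rngs = iter(_substreams(seed, len(conc_multiples)))
    for mult in conc_multiples:
        conc = mult * p.kd
        rng = next(rngs)
        ra = association_trace(ta, conc, p)
        r0 = float(ra[-1])
        rd = dissociation_trace(td, r0, p)
        if drift_per_s:
            ra = ra + drift_per_s * ta
            rd = rd + drift_per_s * (t_assoc + td)
        if sigma > 0:
            ra = ra + rng.normal(0.0, sigma, ta.size)
            rd = rd + rng.normal(0.0, sigma, td.size)
        rows.append(
            pd.DataFrame(
                {"time_s": ta, "conc_M": conc, "phase": "association", "response": ra}
            )
        )
        rows.append(
            pd.DataFrame(
                {"time_s": td, "conc_M": conc, "phase": "dissociation", "response": rd}
            )
        )
    data = pd.concat(rows, ignore_index=True)
    truth = {
        "assay": "bli",
        "seed": seed,
        "kon": p.kon,
        "koff": p.koff,
        "kd": p.kd,
        "rmax": p.rmax,
        "noise_sigma": sigma,
        "drift_per_s": drift_per_s,
    }
    return SyntheticDataset(data=data, truth=truth)


def gen_mds_dataset(
    seed: int,
    kd: float = 83e-9,
    l_tot: float = 10e-9,
    binder_concs: np.ndarray | None = None,
    replicates: int = 3,
    noise_sigma: float = 0.03,
    rh_free: float | None = None,
    rh_complex: float | None = None,
) -> SyntheticDataset:
    """Generate an MDS fraction-bound titration from the exact quadratic.

    Default design: labeled monomer at 10 nM, 12 binder concentrations
    log-spaced from 1 nM to 10 µM, triplicates, additive Gaussian noise of
    0.03 on the fraction-bound scale.  If radius endpoints are given, a
    ``radius_nm`` column (fraction-weighted mean radius with the same noise
    applied on the fraction scale) is included.
    """
    if binder_concs is None:
        binder_concs = np.logspace(-9, -5, 12)
    binder_concs = np.asarray(binder_concs, dtype=float)
    if binder_concs.size == 0:
        raise SynthConfigError("binder_concs must be nonempty")
    if noise_sigma < 0:
        raise SynthConfigError("noise_sigma must be >= 0")
    frac_true = np.array(
        [
            complex_conc_quadratic(EquilibriumSystem(l_tot=l_tot, b_tot=b, kd=kd))
            / l_tot
            for b in binder_concs
        ]
    )
    rows = []
    rngs = iter(_substreams(seed, replicates))
    for rep in range(replicates):
        rng = next(rngs)
        noisy = frac_true + (
            rng.normal(0.0, noise_sigma, binder_concs.size) if noise_sigma > 0 else 0.0
        )
        row = pd.DataFrame(
            {"conc_M": binder_concs, "replicate": rep, "fraction_bound": noisy}
        )
        if rh_free is not None and rh_complex is not None:
            row["radius_nm"] = rh_free + noisy * (rh_complex - rh_free)
        rows.append(row)
    data = pd.concat(rows, ignore_index=True)
    truth = {
        "assay": "mds",
        "seed": seed,
        "kd": kd,
        "l_tot": l_tot,
        "noise_sigma": noise_sigma,
        "rh_free": rh_free,
        "rh_complex": rh_complex,
    }
    return SyntheticDataset(data=data, truth=truth)


def gen_scrambled_targets(
    seed: int, protein: TargetProtein, n: int = 100
) -> list[TargetProtein]:
    """Composition-preserving shuffles of a target sequence (null model).

    Used to compare burial-pattern match counts on a real amyloidogenic
    sequence against sequences of identical composition but random order.
    """
    rng = np.random.default_rng(seed)
    letters = np.array(list(protein.sequence))
    out = []
    for i in range(n):
        out.append(
            TargetProtein(
                f"{protein.name}_shuffle{i}",
                "".join(rng.permutation(letters)),
            )
        )
    return out
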