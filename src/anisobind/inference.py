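"""Binding-constant inference from anisotropy titrations.

Two experiment geometries are supported:

direct titration
    Tracer at fixed concentration, binding sites titrated.  Each well's
    anisotropy is inverted to fractional saturation ``nu_b`` with the
    quantum-yield correction; the free-site concentration is recovered as
    ``sites_total - nu_b * probe_total`` (1:1 stoichiometry), and a
    single-site isotherm ``nu_b = x / (Kd + x)`` is fitted over the free
    concentration x.  This calibrates the tracer's own Ka.

competition (displacement)
    Tracer and sites fixed, an unlabeled competitor titrated.  The
    competitor's Kd is the single free parameter of an exact mass-action
    forward model (tracer Ka known from calibration): predicted
    equilibria are pushed through the observation model and residuals
    are taken in anisotropy space, where the measurement noise is
    additive.

Each replicate series is fitted independently and the per-replicate
dissociation constants are aggregated as mean ± SEM (sample SD, ddof=1),
so the reported uncertainty reflects between-replicate scatter.  Kd is
fitted as log10(Kd) to enforce positivity, with bounds
log10(Kd/nM) in [-2, 7].

Also provides the Z-factor screening-window statistic
``Z = 1 - 3*(sd_p + sd_n)/|mean_p - mean_n|`` for assay quality control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from anisobind.binding_model import (
    AnisotropyObservation,
    ProbeParams,
    anisotropy_forward,
    fraction_bound_from_anisotropy,
)
from anisobind.equilibrium import EquilibriumSystem, solve_competition

__all__ = [
    "Well",
    "TitrationSeries",
    "FitResult",
    "ZFactorResult",
    "estimate_endpoints",
    "fit_direct_kd",
    "fit_competition_kd",
    "zfactor",
    "aggregate_replicates",
    "LOG10_KD_BOUNDS",
]

#: search bounds for log10(Kd / nM): 10 fM to 10 mM
LOG10_KD_BOUNDS = (-2.0, 7.0)

#: observed anisotropy span below this fraction of the probe's dynamic
#: range is treated as "no displacement" (non-binder)
_FLAT_SPAN_FRACTION = 0.05


@dataclass(frozen=True)
class Well:
    """One well of a titration: chemistry plus its measured signal."""

    sites_total: float
    probe_total: float
    r: float
    ligand_total: Optional[float] = None
    It: Optional[float] = None
    replicate_id: int = 1
    well_id: str = ""

    @property
    def observation(self) -> AnisotropyObservation:
        return AnisotropyObservation(r=self.r, It=self.It)


@dataclass
class TitrationSeries:
    """An ordered set of wells sharing one experiment mode and one tracer.

    ``mode`` is ``"direct"`` (sites titrated against fixed tracer) or
    ``"competition"`` (unlabeled competitor titrated against fixed
    tracer + sites).  ``metadata`` carries free-form provenance — for
    synthetic data this includes the generating ground truth.
    """

    mode: Literal["direct", "competition"]
    wells: list[Well]
    probe: ProbeParams
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("direct", "competition"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def replicate_ids(self) -> list[int]:
        seen: dict[int, None] = {}
        for w in self.wells:
            seen.setdefault(w.replicate_id, None)
        return list(seen)

    def replicate(self, rep_id: int) -> list[Well]:
        return [w for w in self.wells if w.replicate_id == rep_id]


@dataclass(frozen=True)
class FitResult:
    """Replicate-aggregated binding-constant estimate.

    ``kd_mean``/``kd_sem`` are in nM; ``kd_sem`` is None for a single
    replicate.  When the data show no displacement (non-binder), no point
    estimate exists: ``is_lower_bound`` is set and ``kd_lower_bound``
    holds the smallest Kd compatible with the flat curve.
    """

    kd_mean: Optional[float]
    kd_sem: Optional[float]
    n_replicates: int
    per_replicate_kd: tuple[float, ...]
    rss: float
    converged: bool
    is_lower_bound: bool = False
    kd_lower_bound: Optional[float] = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def ka_mean(self) -> Optional[float]:
        """Mean association constant, per nM."""
        return None if self.kd_mean is None else 1.0 / self.kd_mean


@dataclass(frozen=True)
class ZFactorResult:
    """Z-factor with the control-group statistics it was computed from."""

    z: float
    mean_positive: float
    sd_positive: float
    mean_negative: float
    sd_negative: float
    n_positive: int
    n_negative: int


def aggregate_replicates(
    per_replicate_kd: Sequence[float],
) -> tuple[float, Optional[float]]:
    """Mean and SEM of per-replicate dissociation constants.

    SEM uses the sample standard deviation (ddof=1) over n replicates,
    ``SD/sqrt(n)``; it is None for a single replicate.
    """
    vals = np.asarray(per_replicate_kd, dtype=float)
    if vals.size == 0:
        raise ValueError("no replicate estimates to aggregate")
    mean = float(vals.mean())
    if vals.size < 2:
        return mean, None
    sem = float(vals.std(ddof=1) / math.sqrt(vals.size))
    return mean, sem


def estimate_endpoints(
    series_free: Sequence[AnisotropyObservation],
    series_bound: Sequence[AnisotropyObservation],
) -> ProbeParams:
    """Calibrate tracer endpoint parameters from control wells.

    ``series_free`` are tracer-only wells; ``series_bound`` are wells with
    saturating sites.  Endpoint anisotropies are the group means and the
    intensity ratio R is the ratio of group-mean intensities.  If either
    group lacks intensities, R is left unset and only the uncorrected
    (R = 1) analysis is possible downstream.
    """
    if not series_free or not series_bound:
        raise ValueError("both control groups must be non-empty")
    rf_vals = np.array([o.r for o in series_free], dtype=float)
    rb_vals = np.array([o.r for o in series_bound], dtype=float)
    rf, rb = float(rf_vals.mean()), float(rb_vals.mean())
    if rb <= rf:
        raise ValueError(
            f"bound-state mean anisotropy ({rb}) does not exceed free-state ({rf}); "
            "controls do not define a binding signal"
        )
    rf_sd = float(rf_vals.std(ddof=1)) if rf_vals.size > 1 else None
    rb_sd = float(rb_vals.std(ddof=1)) if rb_vals.size > 1 else None

    R = R_sd = None
    if all(o.It is not None for o in series_free) and all(
        o.It is not None for o in series_bound
    ):
        if_vals = np.array([o.It for o in series_free], dtype=float)
        ib_vals = np.array([o.It for o in series_bound], dtype=float)
        R = float(ib_vals.mean() / if_vals.mean())
        if if_vals.size > 1 and ib_vals.size > 1:
            # first-order propagation of the ratio's SD
            R_sd = R * math.sqrt(
                (if_vals.std(ddof=1) / if_vals.mean()) ** 2
                + (ib_vals.std(ddof=1) / ib_vals.mean()) ** 2
            )
    return ProbeParams(rf=rf, rb=rb, R=R, rf_sd=rf_sd, rb_sd=rb_sd, R_sd=R_sd)


def _half_point_guess(x: np.ndarray, y: np.ndarray, y_target: float) -> Optional[float]:
    """x at which y first crosses y_target, by linear interpolation."""
    order = np.argsort(x)
    x, y = x[order], y[order]
    for i in range(1, len(y)):
        lo, hi = sorted((y[i - 1], y[i]))
        if lo <= y_target <= hi and y[i] != y[i - 1]:
            frac = (y_target - y[i - 1]) / (y[i] - y[i - 1])
            return float(x[i - 1] + frac * (x[i] - x[i - 1]))
    return None


def _fit_replicate_direct(wells: list[Well], probe: ProbeParams) -> dict:
    """Single-replicate direct-titration fit; returns kd and diagnostics."""
    nu = np.array(
        [
            fraction_bound_from_anisotropy(w.observation, probe).nu_b_raw
            for w in wells
        ]
    )
    sites = np.array([w.sites_total for w in wells], dtype=float)
    probe_tot = np.array([w.probe_total for w in wells], dtype=float)
    # depletion correction: bound probe occupies sites one-to-one
    x_free = sites - nu * probe_tot

    if np.nanmax(nu) < 0.1:
        return {"kd": None, "rss": float(np.sum(nu**2)), "converged": False,
                "message": "no binding signal (max nu_b < 0.1)"}

    guess = _half_point_guess(x_free, nu, 0.5)
    log10_kd0 = np.clip(
        math.log10(guess) if guess and guess > 0 else math.log10(max(x_free.max(), 1.0)),
        *LOG10_KD_BOUNDS,
    )

    def residuals(p: np.ndarray) -> np.ndarray:
        kd = 10.0 ** p[0]
        return nu - x_free / (kd + x_free)

    res = least_squares(
        residuals, x0=[log10_kd0], bounds=([LOG10_KD_BOUNDS[0]], [LOG10_KD_BOUNDS[1]]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    return {
        "kd": 10.0 ** res.x[0],
        "rss": float(2.0 * res.cost),
        "converged": bool(res.success),
        "message": res.message,
        "nfev": int(res.nfev),
    }


def fit_direct_kd(series: TitrationSeries) -> FitResult:
    """Calibrate the tracer's dissociation constant from a direct titration.

    Per replicate: invert each well's anisotropy to ``nu_b`` (quantum-yield
    corrected, unclamped), correct the free-site concentration for tracer
    depletion, and least-squares fit the single-site isotherm
    ``nu_b = x/(Kd + x)``.  Per-replicate Kd values are aggregated as
    mean ± SEM.

    Requires ``series.probe.R``; at least 4 distinct site concentrations
    per replicate.
    """
    if series.mode != "direct":
        raise ValueError(f"expected a direct titration, got mode={series.mode!r}")
    if series.probe.R is None:
        raise ValueError("probe intensity ratio R required for the corrected fit")
    return _fit_by_replicate(series, lambda wells: _fit_replicate_direct(wells, series.probe))


def _fit_replicate_competition(
    wells: list[Well], probe: ProbeParams, probe_ka: float
) -> dict:
    """Single-replicate competition fit in anisotropy space."""
    # control wells (no competitor field) calibrate endpoints, not Kd
    wells = [w for w in wells if w.ligand_total is not None]
    if len({w.ligand_total for w in wells}) < 4:
        raise ValueError(
            "competition fit needs >=4 distinct competitor concentrations"
        )
    wells = sorted(wells, key=lambda w: w.ligand_total)
    r_obs = np.array([w.r for w in wells], dtype=float)
    lig = np.array([w.ligand_total or 0.0 for w in wells], dtype=float)

    # non-binder screen: observed span vs the probe's dynamic range at
    # this occupancy (r at zero competitor down to rf)
    r0 = r_obs[lig == lig.min()].mean()
    span = r0 - r_obs.min()
    full_span = r0 - probe.rf
    if full_span <= 0 or span < _FLAT_SPAN_FRACTION * full_span:
        return {
            "kd": None,
            "rss": float(np.sum((r_obs - r_obs.mean()) ** 2)),
            "converged": True,
            "lower_bound": float(lig.max()),
            "message": "no displacement at the highest competitor concentration",
        }

    def predict(kd_l: float) -> np.ndarray:
        out = np.empty_like(lig)
        for i, (w, lt) in enumerate(zip(wells, lig)):
            state = solve_competition(
                EquilibriumSystem(
                    sites_total=w.sites_total,
                    probe_total=w.probe_total,
                    probe_ka=probe_ka,
                    ligand_total=float(lt),
                    ligand_ka=1.0 / kd_l,
                )
            )
            out[i] = anisotropy_forward(state.probe_saturation, probe).r
        return out

    guess = _half_point_guess(lig, r_obs, (r0 + r_obs.min()) / 2.0)
    log10_kd0 = np.clip(
        math.log10(guess) if guess and guess > 0 else math.log10(max(lig.max() / 10.0, 1.0)),
        *LOG10_KD_BOUNDS,
    )

    def residuals(p: np.ndarray) -> np.ndarray:
        return predict(10.0 ** p[0]) - r_obs

    res = least_squares(
        residuals, x0=[log10_kd0], bounds=([LOG10_KD_BOUNDS[0]], [LOG10_KD_BOUNDS[1]]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    return {
        "kd": 10.0 ** res.x[0],
        "rss": float(2.0 * res.cost),
        "converged": bool(res.success),
        "message": res.message,
        "nfev": int(res.nfev),
    }


def fit_competition_kd(series: TitrationSeries, probe_ka: float) -> FitResult:
    """Fit an unlabeled competitor's Kd from a displacement series.

    The tracer's association constant ``probe_ka`` (per nM, from a prior
    direct calibration) is held fixed; per replicate, the competitor's Kd
    is the single parameter minimizing the squared anisotropy residuals
    of the exact mass-action forward model.  Aggregated as mean ± SEM.

    A series showing no displacement (anisotropy span below 5% of the
    dynamic range) yields a lower bound on Kd — the highest competitor
    concentration tested — flagged via ``is_lower_bound``, never a point
    estimate.
    """
    if series.mode != "competition":
        raise ValueError(f"expected a competition series, got mode={series.mode!r}")
    if series.probe.R is None:
        raise ValueError("probe intensity ratio R required for the forward model")
    if not probe_ka > 0:
        raise ValueError("probe_ka must be positive")
    return _fit_by_replicate(
        series, lambda wells: _fit_replicate_competition(wells, series.probe, probe_ka)
    )


def _fit_by_replicate(series: TitrationSeries, fit_one) -> FitResult:
    """Run a per-replicate fitter over every replicate and aggregate."""
    per_rep: list[float] = []
    lower_bounds: list[float] = []
    rss_total = 0.0
    converged = True
    messages = {}
    for rep in series.replicate_ids:
        wells = series.replicate(rep)
        n_distinct = len(
            {(w.sites_total, w.ligand_total) for w in wells}
        )
        if n_distinct < 4:
            raise ValueError(
                f"replicate {rep} has {n_distinct} distinct concentrations; >=4 required"
            )
        out = fit_one(wells)
        rss_total += out["rss"]
        messages[rep] = out.get("message", "")
        if out.get("lower_bound") is not None:
            lower_bounds.append(out["lower_bound"])
        elif out["kd"] is None or not out["converged"]:
            converged = False
        else:
            per_rep.append(out["kd"])

    if lower_bounds and not per_rep:
        return FitResult(
            kd_mean=None, kd_sem=None, n_replicates=len(series.replicate_ids),
            per_replicate_kd=(), rss=rss_total, converged=True,
            is_lower_bound=True, kd_lower_bound=float(np.mean(lower_bounds)),
            diagnostics={"messages": messages},
        )
    if not per_rep:
        return FitResult(
            kd_mean=None, kd_sem=None, n_replicates=len(series.replicate_ids),
            per_replicate_kd=(), rss=rss_total, converged=False,
            diagnostics={"messages": messages},
        )
    mean, sem = aggregate_replicates(per_rep)
    return FitResult(
        kd_mean=mean, kd_sem=sem, n_replicates=len(per_rep),
        per_replicate_kd=tuple(per_rep), rss=rss_total, converged=converged,
        diagnostics={"messages": messages},
    )


def zfactor(
    positive: Sequence[AnisotropyObservation],
    negative: Sequence[AnisotropyObservation],
) -> ZFactorResult:
    """Screening-window statistic of a plate's control wells.

        Z = 1 - 3*(sd_p + sd_n) / |mean_p - mean_n|

    with sample standard deviations (ddof=1).  Z near 1 means the
    positive (tracer fully bound) and negative (tracer free) control
    bands are far apart relative to their noise; Z > 0.5 is the usual
    screening-quality threshold.  Z is invariant under any positive
    affine rescaling of the anisotropy axis (e.g. mA vs dimensionless).

    Requires at least 3 wells per group and distinct group means.
    """
    if len(positive) < 3 or len(negative) < 3:
        raise ValueError("Z-factor needs >=3 wells in each control group")
    rp = np.array([o.r for o in positive], dtype=float)
    rn = np.array([o.r for o in negative], dtype=float)
    mp, mn = float(rp.mean()), float(rn.mean())
    if mp == mn:
        raise ValueError("control means are identical; Z-factor undefined")
    sp, sn = float(rp.std(ddof=1)), float(rn.std(ddof=1))
    z = 1.0 - 3.0 * (sp + sn) / abs(mp - mn)
    return ZFactorResult(
        z=z, mean_positive=mp, sd_positive=sp, mean_negative=mn, sd_negative=sn,
        n_positive=len(positive), n_negative=len(negative),
    )
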