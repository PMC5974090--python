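"""Exact 1:1 mass-action equilibria with ligand depletion.

At the concentrations an anisotropy assay runs at (tracer and sites both
in the low-nanomolar range, near their Kd), the bound species is a large
fraction of the total, so "free ≈ total" shortcuts and Cheng–Prusoff
style IC50 conversions are invalid.  This module solves the coupled
conservation / mass-action system exactly:

    Ka_p = [probe]_bound  / ([sites]_free * [probe]_free)
    Ka_l = [ligand]_bound / ([sites]_free * [ligand]_free)
    [probe]_free  = [probe]_total  - [probe]_bound
    [ligand]_free = [ligand]_total - [ligand]_bound
    [sites]_free  = [sites]_total  - [ligand]_bound - [probe]_bound

Choosing the free-site concentration x as the single unknown reduces the
whole system to one strictly monotone scalar equation

    x + P*x/(Kd_p + x) + L*x/(Kd_l + x) = T

whose root is guaranteed to lie in [0, T]; a bracketed Brent search finds
it without any risk of spurious roots.  The tracer-only case has the
familiar quadratic closed form.

Concentrations are in nM throughout; association constants per nM
(Kd = 1/Ka in nM).  Stoichiometry is fixed at 1:1 per species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from scipy.optimize import brentq

__all__ = [
    "EquilibriumSystem",
    "EquilibriumState",
    "solve_binary",
    "solve_competition",
    "displacement_curve",
    "ConvergenceError",
    "KA_PER_MOLAR_TO_PER_NM",
]

#: multiply an association constant in M^-1 by this to get nM^-1
KA_PER_MOLAR_TO_PER_NM = 1e-9

#: absolute tolerance on the free-site root, nM
_ROOT_XTOL = 1e-12

#: maximum tolerated conservation violation, nM
_RESIDUAL_TOL = 1e-10


class ConvergenceError(RuntimeError):
    """Equilibrium solve failed to reach the conservation tolerance."""


@dataclass(frozen=True)
class EquilibriumSystem:
    """Total concentrations and binding constants of a binding mixture.

    Parameters
    ----------
    sites_total : float
        Total binding-site concentration, nM.
    probe_total : float
        Total labeled-tracer concentration, nM.
    probe_ka : float
        Tracer association constant, per nM.
    ligand_total, ligand_ka : float, optional
        Unlabeled competitor total (nM) and association constant (per nM);
        leave unset for a tracer-only system.
    """

    sites_total: float
    probe_total: float
    probe_ka: float
    ligand_total: Optional[float] = None
    ligand_ka: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sites_total < 0 or self.probe_total < 0:
            raise ValueError("concentrations must be non-negative")
        if not self.probe_ka > 0:
            raise ValueError("probe_ka must be positive")
        if self.ligand_total is not None and self.ligand_total < 0:
            raise ValueError("ligand_total must be non-negative")
        if self.ligand_ka is not None and not self.ligand_ka > 0:
            raise ValueError("ligand_ka must be positive")

    @property
    def probe_kd(self) -> float:
        return 1.0 / self.probe_ka

    @property
    def ligand_kd(self) -> Optional[float]:
        return None if self.ligand_ka is None else 1.0 / self.ligand_ka

    @property
    def has_ligand(self) -> bool:
        return bool(self.ligand_total) and self.ligand_ka is not None


@dataclass(frozen=True)
class EquilibriumState:
    """Free/bound concentrations of every species at equilibrium (nM).

    ``residual`` is the largest absolute conservation violation across the
    three species balances.
    """

    sites_free: float
    probe_free: float
    probe_bound: float
    ligand_free: float
    ligand_bound: float
    residual: float

    @property
    def probe_saturation(self) -> float:
        """Fraction of tracer bound, nu_b."""
        tot = self.probe_free + self.probe_bound
        return 0.0 if tot == 0 else self.probe_bound / tot


def _state_from_sites_free(system: EquilibriumSystem, x: float) -> EquilibriumState:
    """Derive all bound/free amounts from a free-site concentration x."""
    kd_p = system.probe_kd
    pb = system.probe_total * x / (kd_p + x)
    if system.ligand_total and system.ligand_ka:
        kd_l = 1.0 / system.ligand_ka
        lb = system.ligand_total * x / (kd_l + x)
        lt = system.ligand_total
    else:
        lb = 0.0
        lt = 0.0
    residual = max(
        abs(x + pb + lb - system.sites_total),
        # probe and ligand balances hold by construction but are checked
        abs((system.probe_total - pb) + pb - system.probe_total),
        abs((lt - lb) + lb - lt),
    )
    return EquilibriumState(
        sites_free=x,
        probe_free=system.probe_total - pb,
        probe_bound=pb,
        ligand_free=lt - lb,
        ligand_bound=lb,
        residual=residual,
    )


def solve_binary(system: EquilibriumSystem) -> EquilibriumState:
    """Equilibrium of tracer + sites only (no competitor), closed form.

    The 1:1 balance gives the quadratic whose physical root is

        bound = (S - sqrt(S^2 - 4*P*T)) / 2,   S = P + T + Kd

    evaluated in the numerically stable form ``2*P*T / (S + sqrt(...))``
    to avoid cancellation when binding is weak.

    Raises
    ------
    ValueError
        If the system carries a competitor (use :func:`solve_competition`).
    """
    if system.has_ligand:
        raise ValueError("system has a competitor; use solve_competition")
    P, T, kd = system.probe_total, system.sites_total, system.probe_kd
    S = P + T + kd
    disc = S * S - 4.0 * P * T
    if disc < 0:  # impossible for non-negative P, T and kd > 0
        raise ConvergenceError(f"negative discriminant {disc} in binary solve")
    root = math.sqrt(disc)
    # stable: (S - root) = 4PT / (S + root)
    bound = 0.0 if S + root == 0 else 2.0 * P * T / (S + root)
    state = EquilibriumState(
        sites_free=T - bound,
        probe_free=P - bound,
        probe_bound=bound,
        ligand_free=0.0,
        ligand_bound=0.0,
        residual=max(abs((T - bound) + bound - T), abs((P - bound) + bound - P)),
    )
    if state.residual > _RESIDUAL_TOL:
        raise ConvergenceError(
            f"conservation residual {state.residual:.3e} nM exceeds tolerance"
        )
    return state


def solve_competition(system: EquilibriumSystem) -> EquilibriumState:
    """Equilibrium of tracer + competitor + sites, exact with depletion.

    Solves the monotone scalar conservation equation for the free-site
    concentration on the guaranteed bracket [0, sites_total] with Brent's
    method (absolute tolerance 1e-12 nM), then derives every bound/free
    amount from the root.  With the competitor absent this reproduces
    :func:`solve_binary` exactly (same equation, same root).
    """
    if not system.has_ligand:
        return solve_binary(
            replace(system, ligand_total=None, ligand_ka=None)
        )
    T = system.sites_total
    P, kd_p = system.probe_total, system.probe_kd
    L, kd_l = system.ligand_total, 1.0 / system.ligand_ka

    if T == 0:
        return _state_from_sites_free(system, 0.0)

    def conservation(x: float) -> float:
        return x + P * x / (kd_p + x) + L * x / (kd_l + x) - T

    # f(0) = -T < 0, f(T) >= 0: sign change guaranteed
    x = brentq(conservation, 0.0, T, xtol=_ROOT_XTOL, rtol=8.9e-16)
    # Newton polish: the conservation slope can reach 1 + P/Kd_p + L/Kd_l,
    # so the bracketed root's residual may sit above the mass-balance
    # tolerance; one or two guarded steps pull it to machine level
    for _ in range(2):
        slope = (
            1.0
            + P * kd_p / (kd_p + x) ** 2
            + L * kd_l / (kd_l + x) ** 2
        )
        x = min(max(x - conservation(x) / slope, 0.0), T)
    state = _state_from_sites_free(system, x)
    if state.residual > _RESIDUAL_TOL:
        raise ConvergenceError(
            f"conservation residual {state.residual:.3e} nM exceeds tolerance "
            f"at ligand_total={L} nM"
        )
    return state


def displacement_curve(
    system_base: EquilibriumSystem, ligand_totals: Sequence[float]
) -> list[EquilibriumState]:
    """Solve the competition equilibrium across a competitor dilution series.

    ``system_base`` supplies sites, tracer and both binding constants; the
    competitor total is swept over ``ligand_totals``.  Along an ascending
    series the tracer-bound amount is non-increasing (more competitor can
    only displace more tracer).

    Raises
    ------
    ConvergenceError
        Re-raised with the failing concentration's index if any single
        solve fails.
    """
    if system_base.ligand_ka is None:
        raise ValueError("system_base must carry the competitor's ligand_ka")
    states = []
    for i, lt in enumerate(ligand_totals):
        if lt < 0:
            raise ValueError(f"ligand_totals[{i}] = {lt} is negative")
        try:
            states.append(
                solve_competition(replace(system_base, ligand_total=float(lt)))
            )
        except ConvergenceError as err:
            raise ConvergenceError(
                f"solve failed at ligand_totals[{i}] = {lt} nM: {err}"
            ) from err
    return states
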