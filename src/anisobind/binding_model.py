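"""Photophysical observation model for an anisotropy binding assay.

A small fluorescent tracer tumbles fast in solution and shows a low
anisotropy ``rf``; bound to a large protein it tumbles slowly and shows a
high anisotropy ``rb``.  The measured anisotropy of a mixture is the
*intensity-weighted* average of the two states.  When binding also changes
the quantum yield — common for fluorescein conjugates — the bound state
contributes ``R = Ib/If`` times more photons per molecule, so the naive
linear interpolation between ``rf`` and ``rb`` reports the *fluorescence
fraction* ``Fb``, not the molar fraction bound ``nu_b``.  This module holds
both directions of the corrected two-state model:

forward
    ``nu_b -> (r, It)`` with ``It = If*nu_f + Ib*nu_b`` and
    ``r = (If*nu_f*rf + Ib*nu_b*rb) / It``.

inverse
    ``r -> nu_b = (r - rf) / [(r - rf) + R*(rb - r)]``, which reduces to
    the uncorrected ``(r - rf)/(rb - rf)`` at ``R = 1``.

Anisotropy is stored dimensionless; plate readers often print
milli-anisotropy (mA = r * 1000), which the I/O layer converts with
:func:`from_milli` / :func:`to_milli`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = [
    "ProbeParams",
    "AnisotropyObservation",
    "SaturationValue",
    "anisotropy_forward",
    "fraction_bound_from_anisotropy",
    "fraction_bound_simple",
    "from_milli",
    "to_milli",
]

#: free-state fluorescence intensity, fixed at 1 arbitrary unit; only the
#: bound/free ratio R enters the model, so Ib = R.
I_FREE = 1.0


def from_milli(r_milli: float) -> float:
    """Convert milli-anisotropy (mA) to dimensionless anisotropy."""
    return r_milli / 1000.0


def to_milli(r: float) -> float:
    """Convert dimensionless anisotropy to milli-anisotropy (mA)."""
    return r * 1000.0


@dataclass(frozen=True)
class ProbeParams:
    """Photophysical endpoint parameters of a labeled tracer.

    Parameters
    ----------
    rf : float
        Anisotropy of the free tracer (dimensionless).
    rb : float
        Anisotropy of the fully bound tracer (dimensionless); must exceed
        ``rf``.
    R : float, optional
        Bound-to-free fluorescence intensity ratio ``Ib/If``.  ``None``
        until measured; the quantum-yield-corrected inversion requires it.
    ka : float, optional
        Association constant of the tracer for its site, per nM.  ``None``
        until calibrated by a direct titration.
    rf_sd, rb_sd, R_sd : float, optional
        One-standard-deviation uncertainties of the endpoint estimates.
    """

    rf: float
    rb: float
    R: Optional[float] = None
    ka: Optional[float] = None
    rf_sd: Optional[float] = None
    rb_sd: Optional[float] = None
    R_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.rb > self.rf:
            raise ValueError(
                f"bound-state anisotropy must exceed free-state: rb={self.rb} <= rf={self.rf}"
            )
        if self.R is not None and not self.R > 0:
            raise ValueError(f"intensity ratio R must be positive, got {self.R}")
        if self.ka is not None and not self.ka > 0:
            raise ValueError(f"association constant must be positive, got {self.ka}")

    @property
    def kd(self) -> Optional[float]:
        """Dissociation constant in nM (1/ka), or None if uncalibrated."""
        return None if self.ka is None else 1.0 / self.ka

    @property
    def intensity_bound(self) -> float:
        """Fluorescence intensity of the bound state, Ib = R * If."""
        if self.R is None:
            raise ValueError("intensity ratio R is not set for this probe")
        return self.R * I_FREE


@dataclass(frozen=True)
class AnisotropyObservation:
    """A single anisotropy reading, optionally with total intensity.

    ``r`` is dimensionless anisotropy; ``It`` is total fluorescence
    intensity in arbitrary units (free tracer alone reads 1).  No range
    check at construction: measurement noise may push ``r`` slightly
    outside ``[rf, rb]`` and the inversion handles that explicitly.
    """

    r: float
    It: Optional[float] = None


@dataclass(frozen=True)
class SaturationValue:
    """Fractional saturation of the tracer with its fluorescence split.

    ``nu_b`` is the molar fraction of tracer bound (clamped to [0, 1]);
    ``nu_b_raw`` keeps the unclamped algebraic value so that fitting can
    use noise-faithful residuals.  ``Fb``/``Ff`` are the fractions of total
    emitted intensity contributed by bound/free tracer — these equal
    ``nu_b``/``nu_f`` only when the quantum yield does not change (R = 1).
    ``clamped`` flags observations whose raw value fell outside [0, 1].
    """

    nu_b: float
    nu_b_raw: float
    Fb: float
    clamped: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.nu_b <= 1.0:
            raise ValueError(f"nu_b must lie in [0, 1], got {self.nu_b}")

    @property
    def nu_f(self) -> float:
        return 1.0 - self.nu_b

    @property
    def Ff(self) -> float:
        return 1.0 - self.Fb


def anisotropy_forward(nu_b: float, probe: ProbeParams) -> AnisotropyObservation:
    """Predict the measured anisotropy and total intensity at saturation ``nu_b``.

    Each state contributes photons in proportion to its population and
    per-molecule intensity, so with If = 1 and Ib = R:

        It = nu_f + R * nu_b
        r  = (nu_f * rf + R * nu_b * rb) / It

    Parameters
    ----------
    nu_b : float
        Fraction of tracer bound, in [0, 1].
    probe : ProbeParams
        Endpoint parameters; ``R`` must be set.

    Returns
    -------
    AnisotropyObservation
        Predicted ``r`` (dimensionless) and ``It`` (arbitrary units).
    """
    if not 0.0 <= nu_b <= 1.0:
        raise ValueError(f"nu_b must lie in [0, 1], got {nu_b}")
    Ib = probe.intensity_bound
    nu_f = 1.0 - nu_b
    It = I_FREE * nu_f + Ib * nu_b
    r = (I_FREE * nu_f * probe.rf + Ib * nu_b * probe.rb) / It
    return AnisotropyObservation(r=r, It=It)


def fraction_bound_from_anisotropy(
    obs: AnisotropyObservation, probe: ProbeParams
) -> SaturationValue:
    """Invert a measured anisotropy to fractional saturation, correcting for R.

        nu_b = (r - rf) / [(r - rf) + R * (rb - r)]

    Exact inverse of :func:`anisotropy_forward`.  Readings outside
    ``[rf, rb]`` (noise at the endpoints) yield a raw value outside
    [0, 1]; the returned ``nu_b`` is clamped and ``clamped`` is set, while
    ``nu_b_raw`` preserves the algebraic value for unbiased fitting.

    Also reports the fluorescence fraction ``Fb = (r - rf)/(rb - rf)`` —
    what an uncorrected linear read-out would call "fraction bound".

    Raises
    ------
    ValueError
        If the probe's intensity ratio ``R`` has not been measured.
    """
    if probe.R is None:
        raise ValueError(
            "quantum-yield-corrected inversion requires the intensity ratio R; "
            "measure bound/free intensities or use fraction_bound_simple"
        )
    r = obs.r
    num = r - probe.rf
    den = (r - probe.rf) + probe.R * (probe.rb - r)
    nu_raw = num / den
    Fb = (r - probe.rf) / (probe.rb - probe.rf)
    clamped = not (0.0 <= nu_raw <= 1.0)
    nu = min(1.0, max(0.0, nu_raw))
    return SaturationValue(nu_b=nu, nu_b_raw=nu_raw, Fb=Fb, clamped=clamped)


def fraction_bound_simple(
    obs: AnisotropyObservation, probe: ProbeParams
) -> SaturationValue:
    """Uncorrected fraction bound, ``(r - rf)/(rb - rf)``.

    Valid only for tracers whose quantum yield does not change on binding;
    equals :func:`fraction_bound_from_anisotropy` when ``R = 1``.  For a
    tracer that brightens on binding (R > 1) this overestimates ``nu_b``
    because bright bound molecules dominate the signal.
    """
    nu_raw = (obs.r - probe.rf) / (probe.rb - probe.rf)
    clamped = not (0.0 <= nu_raw <= 1.0)
    nu = min(1.0, max(0.0, nu_raw))
    return SaturationValue(nu_b=nu, nu_b_raw=nu_raw, Fb=nu_raw, clamped=clamped)
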