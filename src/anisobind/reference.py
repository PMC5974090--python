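"""Published assay conditions for the tubulin maytansine-site probe.

The fluorescein-maytansinol tracer (FcMaytansine) reports occupancy of
the maytansine site on beta-tubulin.  These constants — the tracer's
photophysical endpoints, its calibrated affinity, and the dissociation
constants measured by displacement for a panel of maytansine-site
ligands — define the study conditions the synthetic generator emulates
and the ground truths the end-to-end recovery checks use.
"""

from __future__ import annotations

from anisobind.binding_model import ProbeParams

__all__ = [
    "PROBE",
    "PROBE_KD_NM",
    "PROBE_KA_PER_MOLAR",
    "COMPOUND_KD_NM",
    "PROBE_TOTAL_NM",
    "DIRECT_MAX_SITES_NM",
    "COMPETITION_SITES_NM",
]

#: endpoint parameters of FcMaytansine: free anisotropy 0.016, bound
#: anisotropy 0.245, 3.1-fold intensity increase on binding
PROBE = ProbeParams(rf=0.016, rb=0.245, R=3.1, rf_sd=0.001, rb_sd=0.005, R_sd=0.05)

#: tubulin-FcMaytansine dissociation constant from direct titration, nM
PROBE_KD_NM = 6.8

#: the same interaction reported as an association constant, per molar
PROBE_KA_PER_MOLAR = 1.6e8

#: tracer concentration used throughout, nM
PROBE_TOTAL_NM = 10.0

#: top of the tubulin range in direct titrations, nM
DIRECT_MAX_SITES_NM = 400.0

#: fixed tubulin concentration in displacement experiments, nM
COMPETITION_SITES_NM = 4.0

#: displacement-measured dissociation constants of maytansine-site
#: ligands (mean over replicates), nM
COMPOUND_KD_NM = {
    "ansamitocin P3": 15.0,
    "PM060184": 111.0,
    "M9A": 12.6,
    "M9B": 17.5,
    "spongistatin-1": 9.5,
    "disorazole Z": 576.0,
}
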