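"""Calibrated per-template kinetic presets and FRET-level calibrations.

The study reports summary statistics (event fractions, mean times, FRET
levels), not rate constants.  This module derives the preset rate constants
from those printed statistics in closed form and freezes them, so that a
simulated cohort reproduces the printed numbers in expectation:

* ``k_elong`` from the DT8 running time: RNAP covers 1103-10 bp in 5.3 s.
* ``1/k_off_rna`` from the 15 s mean runoff time minus the short-template
  elongation time (91 bp at ``k_elong``).
* ``k_ab = 1/6.6 /s`` from the measured antibody binding wait.
* Per-template ``v_ext`` from the scheme-III high-FRET lag L after antibody
  onset: L = (D - 1 - L_epitope)/v_ext - 1/k_ab with D the downstream end,
  giving 2.91 bp/s (DT3, L = 25 s), 2.45 bp/s (DT2, 31 s), 0.82 bp/s
  (DT1, 105 s).
* ``1/k_rloop_init`` (nucleation delay at the end before the hybrid starts
  growing) from the 74 s mean first-antibody onset on DT1.
* DT8 ``k_nucleate_internal`` from the internal-former fraction: 11% of the
  18% R-loop formers nucleate before RNAP reaches the end (5.3 s exposure).
* DT8 ``f_hindrance`` from the delayed PIFE onset: internal formers reach
  the end at 79 s on average instead of 5.3 s (the "factor 15" delay).

Branch probabilities not printed numerically (DT2, DT4-DT7 and the
runoff/retention splits) are configured once at values consistent with the
qualitative statements of the study; see ``docs/methods.md``.
"""

from __future__ import annotations

import math

from .params import KineticParams

__all__ = [
    "ANCHORS",
    "preset_kinetics",
    "scheme_fret_levels",
]

# Printed summary statistics the presets are derived from.
ANCHORS = {
    "t_run_s": 5.3,                  # NTP injection -> PIFE onset, DT8
    "dt8_end": 1103,                 # downstream end of DT8
    "stall_site": 10,                # transcript length at the stall
    "runoff_time_s": 15.0,           # mean Cy3 loss since injection, DT1
    "ab_wait_s": 6.6,                # antibody binding wait per epitope
    "ab_onset_s": 74.0,              # mean first-antibody onset, DT1
    "highfret_lag_s": {"DT1": 105.0, "DT2": 31.0, "DT3": 25.0},
    "rloop_fraction": {"DT1": 0.73, "DT3": 0.084},
    "dt8_rloop_fraction": 0.18,      # Alexa-positive fraction of DT8
    "dt8_internal_fraction": 0.11,   # internal formers among R-loop formers
    "t_run_hindered_s": 79.0,        # delayed PIFE onset of internal formers
    "active_fraction": 0.97,         # complexes showing the resume FRET drop
    "pife_window_bp": 15.0,          # RNAP-dye distance triggering PIFE
}

K_ELONG = (ANCHORS["dt8_end"] - ANCHORS["stall_site"]) / ANCHORS["t_run_s"]

_SHORT_RUN = (101 - ANCHORS["stall_site"]) / K_ELONG  # elongation time, DT1-7
MEAN_DISSOCIATION_S = ANCHORS["runoff_time_s"] - _SHORT_RUN

_L_EPITOPE = 8.0


def _v_ext_from_lag(lag_s: float, downstream_end: int = 101) -> float:
    """Invert the scheme-III high-FRET lag for the border extension speed.

    The border travels from the downstream end to +1; the antibody onset
    trails nucleation by L_epitope/v_ext + the binding wait, so
    lag = (D - 1 - L_epitope)/v_ext - ab_wait.
    """
    return (downstream_end - 1 - _L_EPITOPE) / (lag_s + ANCHORS["ab_wait_s"])


V_EXT = {k: _v_ext_from_lag(v) for k, v in ANCHORS["highfret_lag_s"].items()}

# Nucleation delay at the end: mean antibody onset = elongation time +
# nucleation delay + eligibility growth + binding wait (DT1 geometry).
MEAN_INIT_DELAY_S = (
    ANCHORS["ab_onset_s"]
    - _SHORT_RUN
    - _L_EPITOPE / V_EXT["DT1"]
    - ANCHORS["ab_wait_s"]
)

# --- DT8: internal R-loops and elongation hindrance ---
_P_INTERNAL = ANCHORS["dt8_internal_fraction"] * ANCHORS["dt8_rloop_fraction"]
K_NUCLEATE_DT8 = -math.log(1.0 - _P_INTERNAL) / ANCHORS["t_run_s"]

# Unhindered time to the PIFE trigger point (pife_window bp short of the end).
T_PIFE_DT8 = (
    ANCHORS["dt8_end"] - ANCHORS["pife_window_bp"] - ANCHORS["stall_site"]
) / K_ELONG


def _f_hindrance_dt8() -> float:
    # Internal nucleation happens at t_n ~ Exp(k) truncated to [0, T_pife];
    # afterwards the remaining run takes (T_pife - t_n)/f, so
    # E[t_run] = m + (T_pife - m)/f with m the truncated-exponential mean.
    k, T = K_NUCLEATE_DT8, T_PIFE_DT8
    m = 1.0 / k - T * math.exp(-k * T) / (1.0 - math.exp(-k * T))
    return (T - m) / (ANCHORS["t_run_hindered_s"] - m)


F_HINDRANCE_DT8 = _f_hindrance_dt8()

# Terminal-branch R-loop probability so that internal + terminal formers
# total the printed Alexa-positive fraction.
_P_RLOOP_DT8 = (ANCHORS["dt8_rloop_fraction"] - _P_INTERNAL) / (1.0 - _P_INTERNAL)

# Branch probabilities (p_rloop, p_runoff, p_retention).  DT1 and DT3
# R-loop fractions are printed; the rest are configured values consistent
# with the reported trends (retention rare except on the stalling-prone
# DT5; runoff takes the remainder).
_P_BRANCH = {
    "DT1": (0.73, 0.25, 0.02),
    "DT2": (0.60, 0.37, 0.03),
    "DT3": (0.084, 0.886, 0.03),
    "DT4": (0.080, 0.890, 0.03),
    "DT5": (0.050, 0.450, 0.50),
    "DT6": (0.028, 0.942, 0.03),
    "DT7": (0.35, 0.62, 0.03),
    "DT8": (_P_RLOOP_DT8, 1.0 - _P_RLOOP_DT8 - 0.02, 0.02),
}


def preset_kinetics(template_name: str, **overrides) -> KineticParams:
    """Calibrated :class:`KineticParams` for a template preset.

    Scheme variants (``DT3-I`` etc.) share the kinetics of their base
    template.  Keyword overrides are applied last.
    """
    base = template_name.split("-")[0]
    if base not in _P_BRANCH:
        raise ValueError(f"no kinetic preset for template {template_name!r}")
    kw = dict(
        k_elong=K_ELONG,
        p_branch=_P_BRANCH[base],
        k_off_rna=1.0 / MEAN_DISSOCIATION_S,
        v_ext=V_EXT.get(base, V_EXT["DT3"]),
        k_ab=1.0 / ANCHORS["ab_wait_s"],
        L_epitope=_L_EPITOPE,
        epitope_spacing=30.0,
        k_rloop_init=1.0 / MEAN_INIT_DELAY_S,
        p_inactive=1.0 - ANCHORS["active_fraction"],
    )
    if base == "DT8":
        # The 18% Alexa-positive fraction is quoted against all complexes
        # carrying both dyes, not an activity-filtered subset.
        kw.update(
            k_nucleate_internal=K_NUCLEATE_DT8,
            f_hindrance=F_HINDRANCE_DT8,
            p_inactive=0.0,
        )
    kw.update(overrides)
    return KineticParams(**kw)


# Apparent FRET levels of each labeling scheme, calibrated to the printed
# values and frozen; the photophysics module inverts these through the
# Foerster relation to fixed dye separations.
#   scheme III: stalled complex 0.69; border-at-+1 return level 0.75 (the
#     printed criterion is "> 0.7"; the exact high level is a chosen value).
#   scheme II:  0.21 before the border passes the labeled region, 0.64 after.
#   scheme I:   end dyes paired 0.80, separated by the R-loop 0.10 (levels
#     not printed; chosen high/low values).
def scheme_fret_levels(scheme: str) -> tuple[float, float]:
    """(pre, post) apparent FRET levels for a labeling scheme."""
    levels = {
        "III": (0.69, 0.75),
        "II": (0.21, 0.64),
        "I": (0.80, 0.10),
        "end": (0.0, 0.0),
    }
    if scheme not in levels:
        raise ValueError(f"unknown scheme {scheme!r}")
    return levels[scheme]
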