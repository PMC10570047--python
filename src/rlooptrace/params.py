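"""Parameter containers: kinetics, optics/photophysics and classification.

All three are plain dataclasses with validation in ``__post_init__`` and
YAML round-tripping via :func:`load_params_yaml` / :func:`save_params_yaml`.
Template-specific calibrated presets live in :mod:`rlooptrace.calibration`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "KineticParams",
    "OpticsParams",
    "ClassifyConfig",
    "load_params_yaml",
    "save_params_yaml",
]


@dataclass
class KineticParams:
    """Rate constants and branch probabilities of the kinetic state machine.

    Parameters
    ----------
    k_elong : float
        Elongation speed after NTP injection, bp/s.
    p_branch : tuple
        ``(p_rloop, p_runoff, p_retention)`` drawn at downstream-end arrival;
        must sum to 1.
    k_off_rna : float
        RNA dissociation rate at the downstream end (runoff branch), 1/s.
    v_ext : float
        R-loop upstream-border extension speed, bp/s.
    k_ab : float
        Antibody binding rate per available epitope, 1/s (mean wait 1/k_ab
        for a single epitope).
    L_epitope : float
        Minimum RNA-DNA hybrid length for S9.6 binding, bp.
    epitope_spacing : float
        Hybrid growth per additional binding site, bp.
    k_rloop_init : float
        R-loop nucleation rate after end arrival on the R-loop branch, 1/s.
    k_nucleate_internal : float
        Internal R-loop nucleation rate while elongating, 1/s (long templates).
    f_hindrance : float
        Elongation-rate multiplier once an internal R-loop trails RNAP, in
        (0, 1].
    k_rnaseh : float
        Hybrid digestion rate when RNase H is supplied, 1/s.
    k_reinit : float
        Next-round initiation attempt rate when holoenzyme is supplied, 1/s.
    p_inactive : float
        Fraction of complexes that never resume transcription (excluded by
        the active filter downstream).
    t_obs : float
        Observation window, s.
    """

    k_elong: float = 206.2264150943396
    p_branch: tuple[float, float, float] = (0.73, 0.25, 0.02)
    k_off_rna: float = 1.0 / 14.558733773963093
    v_ext: float = 2.9113924050632907
    k_ab: float = 1.0 / 6.6
    L_epitope: float = 8.0
    epitope_spacing: float = 30.0
    k_rloop_init: float = 1.0 / 57.25438928280718
    k_nucleate_internal: float = 0.0
    f_hindrance: float = 1.0
    k_rnaseh: float = 0.05
    k_reinit: float = 0.02
    p_inactive: float = 0.03
    t_obs: float = 600.0

    def __post_init__(self) -> None:
        p = self.p_branch = tuple(float(x) for x in self.p_branch)
        if len(p) != 3 or any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
            raise ValueError(
                "p_branch must be three non-negative probabilities summing to 1"
            )
        for name in (
            "k_elong", "k_off_rna", "v_ext", "k_ab", "L_epitope",
            "epitope_spacing", "k_rloop_init", "k_nucleate_internal",
            "k_rnaseh", "k_reinit",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if p[0] > 0 and self.v_ext <= 0:
            raise ValueError("v_ext must be > 0 when p_rloop > 0")
        if not 0 < self.f_hindrance <= 1:
            raise ValueError("f_hindrance must be in (0, 1]")
        if not 0 <= self.p_inactive < 1:
            raise ValueError("p_inactive must be in [0, 1)")
        if self.t_obs <= 0:
            raise ValueError("t_obs must be > 0")

    def replace(self, **kw) -> "KineticParams":
        return dataclasses.replace(self, **kw)


@dataclass
class OpticsParams:
    """Photophysics of the four-channel TIRF readout.

    FRET follows E = 1/(1 + (r/R0)^6) with dye separations measured as
    contour distance along the nucleic acid (``bp_to_nm`` nm per bp). With
    ``gamma`` = 1 the noiseless donor+acceptor sum at green excitation is
    I_total + 2*background while both dyes are alive.
    """

    R0: float = 6.0                 # Foerster radius, nm
    gamma: float = 1.0              # detection-correction factor
    bp_to_nm: float = 0.34          # contour length per bp, nm
    I_total: float = 1000.0         # summed donor+acceptor counts/frame
    I_ab: float = 500.0             # Alexa-488 counts/frame per bound antibody
    I_red: float = 600.0            # Cy5 counts/frame at direct excitation
    pife_factor: float = 1.6        # Cy5 enhancement while RNAP is nearby
    pife_window: float = 15.0       # RNAP-dye distance triggering PIFE, bp
    background: float = 100.0       # counts/frame per channel
    noise_sd: float = 30.0          # additive Gaussian noise, counts/frame
    k_bleach: float = 3e-5          # per-fluorophore bleaching rate, 1/s
    frame_dt: float = 0.5           # camera binning time, s (0.2 or 0.5)
    pre_time: float = 10.0          # recording before NTP injection, s

    def __post_init__(self) -> None:
        if self.R0 <= 0:
            raise ValueError("R0 must be > 0")
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be > 0")
        if self.pife_factor < 1:
            raise ValueError("pife_factor must be >= 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.noise_sd < 0 or self.k_bleach < 0 or self.background < 0:
            raise ValueError("noise_sd, k_bleach, background must be >= 0")

    def replace(self, **kw) -> "OpticsParams":
        return dataclasses.replace(self, **kw)


@dataclass
class ClassifyConfig:
    """Thresholds for step detection and the event taxonomy.

    Intensity thresholds are in camera counts and default to half the
    expected step size of each channel under the default optics; all are
    config-exposed because the original study's criteria are unpublished.
    """

    gamma: float = 1.0
    background: float = 100.0
    min_total: float = 200.0        # E undefined below this donor+acceptor sum
    smoothing_width: int = 3        # median-filter width, frames
    min_dwell_frames: int = 3       # frames a crossing must be sustained
    baseline_frames: int = 20       # frames used for the robust baseline
    fret_min_delta: float = 0.25    # E step for resume/active detection
    active_window: float = 30.0     # latest allowed resume drop, s
    active_filter: str = "auto"     # 'auto' | 'on' | 'off'
    ab_min_delta: float = 250.0     # Alexa-488 onset threshold, counts
    ab_step: float = 500.0          # counts per bound antibody (= I_ab)
    cy3_min_delta: float = 500.0    # drop in donor+acceptor marking Cy3 loss
    cy3_total: float = 1000.0       # expected donor+acceptor sum (= I_total)
    pife_min_delta: float = 180.0   # red-excitation onset threshold, counts
    high_fret_threshold: float = 0.7

    def __post_init__(self) -> None:
        if self.min_dwell_frames < 1:
            raise ValueError("min_dwell_frames must be >= 1")
        if self.smoothing_width < 1 or self.smoothing_width % 2 == 0:
            raise ValueError("smoothing_width must be a positive odd integer")
        if self.active_filter not in ("auto", "on", "off"):
            raise ValueError("active_filter must be 'auto', 'on' or 'off'")

    @classmethod
    def from_optics(cls, optics: OpticsParams, **kw) -> "ClassifyConfig":
        """Derive channel thresholds from the optics used to render."""
        defaults = dict(
            gamma=optics.gamma,
            background=optics.background,
            min_total=0.2 * optics.I_total,
            ab_min_delta=0.5 * optics.I_ab,
            ab_step=optics.I_ab,
            cy3_min_delta=0.5 * optics.I_total,
            cy3_total=optics.I_total,
            pife_min_delta=0.5 * (optics.pife_factor - 1.0) * optics.I_red,
        )
        defaults.update(kw)
        return cls(**defaults)

    def replace(self, **kw) -> "ClassifyConfig":
        return dataclasses.replace(self, **kw)


_SECTIONS = {
    "kinetics": KineticParams,
    "optics": OpticsParams,
    "classify": ClassifyConfig,
}


def save_params_yaml(path: str | Path, **sections) -> None:
    """Write parameter objects to YAML, one stanza per section.

    ``save_params_yaml(p, kinetics=kp, optics=op, classify=cc)``; any subset
    of sections may be given.
    """
    doc = {}
    for name, obj in sections.items():
        if name not in _SECTIONS:
            raise ValueError(f"unknown section {name!r}")
        d = dataclasses.asdict(obj)
        if "p_branch" in d:
            d["p_branch"] = list(d["p_branch"])
        doc[name] = d
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_params_yaml(path: str | Path) -> dict:
    """Read a YAML written by :func:`save_params_yaml`; returns a dict of
    parameter objects keyed by section name."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    for name, payload in doc.items():
        if name not in _SECTIONS:
            raise ValueError(f"unknown section {name!r} in {path}")
        out[name] = _SECTIONS[name](**payload)
    return out
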