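"""Map ground-truth trajectories to observable four-channel fluorescence
traces: FRET, PIFE, stepwise antibody signal, photobleaching and noise.

Channels (names follow excitation/emission):

* ``donor_em_green_ex``    - Cy3 emission at 532 nm excitation
* ``acceptor_em_green_ex`` - Cy5 emission at 532 nm excitation (FRET)
* ``acceptor_em_red_ex``   - Cy5 emission at 640 nm excitation (PIFE readout)
* ``ab_em_blue_ex``        - Alexa-488 emission at 473 nm excitation

The dye-separation model treats separations as contour distance along the
nucleic acid (``bp_to_nm`` nm per bp).  The effective separations of each
labeling scheme are frozen so that the apparent FRET levels match the
calibrated values in :mod:`rlooptrace.calibration`; in particular the RNA
5'-end sits at a fixed stall-proximal exit position while in the elongation
complex, moves away with the polymerase during elongation, and returns to
the promoter-proximal position once the R-loop border encloses it.

Frames integrate the state at the frame midpoint; recording starts
``pre_time`` seconds before NTP injection, so traces carry negative times
for the stalled baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import scheme_fret_levels
from .params import OpticsParams
from .simulate import MolecularState, StateTrajectory
from .templates import TemplateSpec

__all__ = [
    "Trace",
    "fret_efficiency",
    "separation_bp_for_E",
    "dye_distance",
    "render_trace",
    "render_cohort",
    "CHANNELS",
]

CHANNELS = (
    "donor_em_green_ex",
    "acceptor_em_green_ex",
    "acceptor_em_red_ex",
    "ab_em_blue_ex",
)


@dataclass
class Trace:
    """Per-molecule four-channel intensity time series.

    ``t`` holds frame *start* times (s, negative before NTP injection);
    onset times downstream are reported on this grid.
    """

    molecule_id: int
    frame_dt: float
    t: np.ndarray
    channels: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)
    ground_truth: StateTrajectory | None = None

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1 or lengths.pop() != len(self.t):
            raise ValueError("all channel arrays must match the time axis")
        for name, arr in self.channels.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite intensities in channel {name}")

    @property
    def n_frames(self) -> int:
        return len(self.t)

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]


def fret_efficiency(r, R0: float):
    """Foerster efficiency E = 1 / (1 + (r/R0)^6); monotone decreasing in r."""
    if R0 <= 0:
        raise ValueError("R0 must be > 0")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be >= 0")
    out = 1.0 / (1.0 + (r / R0) ** 6)
    return out if out.shape else float(out)


def separation_bp_for_E(E: float, optics: OpticsParams) -> float:
    """Contour separation (bp) whose Foerster efficiency equals ``E``."""
    if E >= 1.0:
        return 0.0
    if E <= 0.0:
        return np.inf
    r_nm = optics.R0 * (1.0 / E - 1.0) ** (1.0 / 6.0)
    return r_nm / optics.bp_to_nm


def _scheme_separations(template: TemplateSpec, optics: OpticsParams):
    pre, post = scheme_fret_levels(template.scheme)
    return separation_bp_for_E(pre, optics), separation_bp_for_E(post, optics)


# ---------------------------------------------------------------------------
def _effective_separation_bp(
    traj: StateTrajectory,
    template: TemplateSpec,
    optics: OpticsParams,
    t: np.ndarray,
) -> np.ndarray:
    """Effective Cy3-Cy5 contour separation (bp) at each time."""
    scheme = template.scheme
    sep_pre, sep_post = _scheme_separations(template, optics)

    if scheme in ("III", "end"):
        # Cy3 on the RNA 5'-end, Cy5 on DNA.  The 5'-end's effective
        # position is the stall-proximal exit (calibrated so the stalled
        # scheme-III complex reads the printed E), travels with the
        # polymerase during elongation, and returns near +1 once the
        # R-loop border encloses it.
        cy5_pos = template.dye("Cy5").position
        lev_pre, lev_post = scheme_fret_levels("III")
        p5_stall = 8.0 - separation_bp_for_E(lev_pre, optics)
        p5_return = 8.0 - separation_bp_for_E(lev_post, optics)
        pos = np.asarray(traj.rnap_position(t), dtype=float)
        moving = np.asarray(t) > 0 if traj.active else np.zeros(len(t), bool)
        p5 = np.where(
            moving,
            p5_stall + (np.nan_to_num(pos, nan=template.stall_site)
                        - template.stall_site),
            p5_stall,
        )
        border = np.asarray(traj.rloop_upstream_border(t))
        enclosed = (~np.isnan(border)) & (border <= 1.0)
        p5 = np.where(enclosed, p5_return, p5)
        return np.abs(cy5_pos - p5)

    if scheme == "II":
        # Both dyes on the nontemplate strand around the mid-template
        # region; the apparent separation tightens when the R-loop border
        # passes the downstream-most labeled position.
        inner = min(lab.position for lab in template.dye_labels)
        border = np.asarray(traj.rloop_upstream_border(t))
        covered = (~np.isnan(border)) & (border <= inner)
        return np.where(covered, sep_post, sep_pre)

    if scheme == "I":
        # Dyes paired across the two strands at the downstream end; R-loop
        # nucleation there separates them.
        end_rloop = traj.t_rloop_init is not None and not traj.internal
        if not end_rloop:
            return np.full(len(t), sep_pre)
        t = np.asarray(t)
        separated = (t >= traj.t_rloop_init) & (t < traj.t_hybrid_end)
        return np.where(separated, sep_post, sep_pre)

    raise ValueError(f"unknown scheme {scheme!r}")


def dye_distance(
    template: TemplateSpec,
    state: MolecularState,
    pair: tuple[str, str] = ("Cy3", "Cy5"),
    optics: OpticsParams | None = None,
    traj: StateTrajectory | None = None,
) -> float:
    """Cy3-Cy5 distance (nm) in a given molecular state.

    ``pair`` must name two distinct dyes present on the template.  For the
    border-state-dependent schemes the surrounding trajectory is needed to
    resolve the state; if omitted, a minimal stand-in trajectory matching
    ``state`` is used.
    """
    if pair[0] == pair[1]:
        raise ValueError("pair must name two distinct dyes")
    for dye in pair:
        template.dye(dye)  # raises KeyError if absent
    optics = optics or OpticsParams()
    if traj is None:
        from .params import KineticParams
        from .simulate import simulate_molecule

        traj = simulate_molecule(
            template,
            KineticParams(p_branch=(1, 0, 0), p_inactive=0.0),
            seed=0,
        )
        traj = traj.replace(active=not np.isnan(state.rnap_pos)
                            and state.rnap_pos > template.stall_site)
    # evaluate at a time consistent with the state
    t_eval = 0.0
    if not np.isnan(state.rloop_upstream_border) and traj.t_rloop_init is not None:
        h = (state.rloop_downstream_border - state.rloop_upstream_border)
        t_eval = traj.t_rloop_init + h / traj.params.v_ext
    sep = _effective_separation_bp(traj, template, optics, np.asarray([t_eval]))[0]
    return float(sep * optics.bp_to_nm)


# ---------------------------------------------------------------------------
def frame_times(optics: OpticsParams, t_obs: float) -> np.ndarray:
    """Frame start times from -pre_time to t_obs."""
    n_pre = int(round(optics.pre_time / optics.frame_dt))
    n_obs = int(np.ceil(t_obs / optics.frame_dt))
    return (np.arange(n_pre + n_obs) - n_pre) * optics.frame_dt


def render_trace(
    traj: StateTrajectory,
    optics: OpticsParams,
    seed: int,
    template: TemplateSpec | None = None,
) -> Trace:
    """Render one trajectory into a four-channel :class:`Trace`.

    ``template`` overrides the trajectory's own template, which lets the
    same ground truth be imaged under different labeling schemes (the
    scheme variants share identical kinetics).
    """
    template = template or traj.template
    rng = np.random.default_rng(seed)
    t0 = frame_times(optics, traj.t_obs)
    tm = t0 + optics.frame_dt / 2.0  # state sampled at frame midpoints

    # photobleaching (clock starts with the recording)
    if optics.k_bleach > 0:
        t_bleach_cy3 = t0[0] + rng.exponential(1.0 / optics.k_bleach)
        t_bleach_cy5 = t0[0] + rng.exponential(1.0 / optics.k_bleach)
    else:
        t_bleach_cy3 = t_bleach_cy5 = np.inf

    cy3_on_rna = template.dye("Cy3").strand == "RNA"
    rna = np.asarray(traj.rna_present(tm))
    cy3_alive = (tm < t_bleach_cy3) & (rna if cy3_on_rna else True)
    try:
        cy5 = template.dye("Cy5")
        has_cy5 = True
    except KeyError:
        has_cy5 = False
    cy5_alive = (tm < t_bleach_cy5) if has_cy5 else np.zeros(len(tm), bool)

    sep = _effective_separation_bp(traj, template, optics, tm)
    E = np.asarray(fret_efficiency(sep * optics.bp_to_nm, optics.R0))

    bg = optics.background
    noise = (
        (lambda: rng.normal(0.0, optics.noise_sd, len(tm)))
        if optics.noise_sd > 0
        else (lambda: 0.0)
    )
    E_eff = E * cy5_alive
    donor = bg + optics.I_total * (1.0 - E_eff) * cy3_alive + noise()
    acceptor = bg + optics.gamma * optics.I_total * E_eff * cy3_alive + noise()

    if has_cy5:
        rnap = np.asarray(traj.rnap_position(tm))
        near = np.abs(rnap - cy5.position) <= optics.pife_window
        near &= ~np.isnan(rnap)
        pife = np.where(near, optics.pife_factor, 1.0)
        red = bg + optics.I_red * pife * cy5_alive + noise()
    else:
        red = bg + np.zeros(len(tm)) + noise()

    n_ab = np.asarray(traj.n_antibody(tm))
    ab = bg + optics.I_ab * n_ab + noise()

    return Trace(
        molecule_id=traj.molecule_id,
        frame_dt=optics.frame_dt,
        t=t0,
        channels={
            "donor_em_green_ex": donor,
            "acceptor_em_green_ex": acceptor,
            "acceptor_em_red_ex": red,
            "ab_em_blue_ex": ab,
        },
        provenance={"seed": int(seed), "scheme": template.scheme,
                    "template": template.name},
        ground_truth=traj,
    )


def render_cohort(
    trajs: list[StateTrajectory],
    optics: OpticsParams,
    seed: int,
    template: TemplateSpec | None = None,
) -> list[Trace]:
    """Render a cohort with per-molecule seeds derived from ``seed``."""
    out = []
    for i, traj in enumerate(trajs):
        ss = np.random.SeedSequence([int(seed), int(i)])
        out.append(
            render_trace(
                traj, optics, int(ss.generate_state(1, dtype=np.uint32)[0]),
                template=template,
            )
        )
    return out
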