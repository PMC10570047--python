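"""Stochastic simulation of the transcription -> DSB-sensing -> R-loop
state machine for single immobilized template molecules.

One molecule is simulated per call.  The model (time origin t = 0 at NTP
injection, 1-based template coordinates):

* A fraction ``p_inactive`` of complexes never resumes; the rest restart
  elongation from the stall site at ``k_elong`` bp/s.
* While elongating, an internal R-loop may nucleate behind the polymerase
  (rate ``k_nucleate_internal``); from then on elongation is slowed by the
  factor ``f_hindrance``.
* On arrival at the downstream end (the DSB mimic) a branch is drawn:
  R-loop / runoff / retention with the per-template ``p_branch``.
  - R-loop: after an exponential nucleation delay (``k_rloop_init``) the
    RNA-DNA hybrid nucleates at the end; its downstream border stays put
    while the upstream border migrates toward +1 at ``v_ext`` bp/s.
  - Runoff: the transcript dissociates after an Exp(``k_off_rna``) wait.
  - Retention: the RNA stays bound with no R-loop through ``t_obs``.
* S9.6 antibody binding is a Poisson process gated by hybrid length: the
  first epitope opens at ``L_epitope`` bp and one more per
  ``epitope_spacing`` bp of further growth; each open, unoccupied epitope
  binds at rate ``k_ab``.

RNase H addition and next-round initiation pressure are modelled as
post-hoc operators on completed trajectories (:func:`apply_rnaseh`,
:func:`simulate_reinitiation`), mirroring the buffer-exchange experiments.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .params import KineticParams
from .templates import TemplateSpec, build_template

__all__ = [
    "StateTrajectory",
    "MolecularState",
    "simulate_molecule",
    "simulate_cohort",
    "apply_rnaseh",
    "simulate_reinitiation",
    "molecule_seed",
]

_BRANCHES = ("rloop", "runoff", "retention")


class MolecularState(NamedTuple):
    """Ground-truth state of one molecule at one instant."""

    rnap_pos: float           # nan once the polymerase has left the template
    transcript_len: float
    rloop_upstream_border: float   # nan if no hybrid
    rloop_downstream_border: float
    n_antibody: int
    rna_present: bool


@dataclass
class StateTrajectory:
    """Timed ground truth for one molecule over [0, t_obs].

    The trajectory is stored as landmark times plus the piecewise-linear
    motion they imply; ``events`` renders the conventional tidy event list
    and the ``*_at`` methods evaluate the state at arbitrary times
    (vectorized over numpy arrays).
    """

    molecule_id: int
    seed: int
    template: TemplateSpec
    params: KineticParams
    active: bool
    branch: str | None            # None for inactive molecules
    internal: bool = False        # R-loop nucleated behind the polymerase
    t_arrive: float | None = None
    t_internal: float | None = None
    internal_pos: float | None = None
    t_rloop_init: float | None = None
    rloop_downstream: float | None = None
    t_rna_loss: float | None = None
    t_digested: float | None = None
    t_hybrid_end: float = math.inf
    ab_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    reinit_events: tuple[tuple[float, str], ...] = ()

    # -- derived landmarks -------------------------------------------------
    @property
    def t_obs(self) -> float:
        return self.params.t_obs

    @property
    def hybrid_max(self) -> float | None:
        """Largest hybrid length the R-loop can reach, bp."""
        if self.rloop_downstream is None:
            return None
        return self.rloop_downstream - 1.0

    @property
    def t_eligible(self) -> float | None:
        """Time the hybrid first reaches ``L_epitope`` (antibody eligibility)."""
        if self.t_rloop_init is None:
            return None
        p = self.params
        if self.hybrid_max < p.L_epitope:
            return None
        return self.t_rloop_init + p.L_epitope / p.v_ext

    @property
    def t_border_p1(self) -> float | None:
        """Time the upstream border reaches +1 (full extension)."""
        if self.t_rloop_init is None:
            return None
        t = self.t_rloop_init + self.hybrid_max / self.params.v_ext
        return t if t <= self.t_hybrid_end else None

    # -- state functions ---------------------------------------------------
    def rnap_position(self, t):
        """RNAP active-site template position; nan after it leaves."""
        t = np.asarray(t, dtype=float)
        p, tpl = self.params, self.template
        pos = np.full(t.shape, float(tpl.stall_site))
        if self.active:
            moving = t > 0
            if self.t_internal is None:
                pos = np.where(moving, tpl.stall_site + p.k_elong * t, pos)
            else:
                tn, xn = self.t_internal, self.internal_pos
                pre = tpl.stall_site + p.k_elong * np.minimum(t, tn)
                post = p.k_elong * p.f_hindrance * np.maximum(t - tn, 0.0)
                pos = np.where(moving, pre + post, pos)
            pos = np.minimum(pos, float(tpl.downstream_end))
            if self.branch == "runoff" and self.t_rna_loss is not None:
                pos = np.where(t >= self.t_rna_loss, np.nan, pos)
        return pos if pos.shape else float(pos)

    def transcript_length(self, t):
        pos = np.asarray(self.rnap_position(t), dtype=float)
        return np.where(np.isnan(pos), np.nan, pos)

    def rloop_upstream_border(self, t):
        """Upstream hybrid border; nan where no hybrid exists."""
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, np.nan)
        if self.t_rloop_init is not None:
            grow = (t >= self.t_rloop_init) & (t < self.t_hybrid_end)
            border = np.maximum(
                self.rloop_downstream - self.params.v_ext * (t - self.t_rloop_init),
                1.0,
            )
            out = np.where(grow, border, out)
        return out if out.shape else float(out)

    def hybrid_length(self, t):
        t = np.asarray(t, dtype=float)
        if self.rloop_downstream is None:
            z = np.zeros(t.shape)
            return z if z.shape else 0.0
        border = np.asarray(self.rloop_upstream_border(t))
        h = np.where(np.isnan(border), 0.0, self.rloop_downstream - border)
        return h if h.shape else float(h)

    def n_antibody(self, t):
        """Bound-antibody count; the signal ends with the hybrid."""
        t = np.asarray(t, dtype=float)
        n = np.searchsorted(self.ab_times, t, side="right").astype(float)
        n = np.where(t >= self.t_hybrid_end, 0.0, n)
        return n if n.shape else float(n)

    def rna_present(self, t):
        t = np.asarray(t, dtype=float)
        ok = np.ones(t.shape, dtype=bool)
        if self.t_rna_loss is not None:
            ok &= t < self.t_rna_loss
        return ok if ok.shape else bool(ok)

    def state_at(self, t: float) -> MolecularState:
        return MolecularState(
            rnap_pos=float(self.rnap_position(t)),
            transcript_len=float(self.transcript_length(t)),
            rloop_upstream_border=float(self.rloop_upstream_border(t)),
            rloop_downstream_border=(
                float(self.rloop_downstream)
                if self.t_rloop_init is not None
                and self.t_rloop_init <= t < self.t_hybrid_end
                else float("nan")
            ),
            n_antibody=int(self.n_antibody(t)),
            rna_present=bool(self.rna_present(t)),
        )

    # -- event list --------------------------------------------------------
    @property
    def events(self) -> list[tuple[float, str, dict]]:
        """Tidy, time-ordered event list for export."""
        ev: list[tuple[float, str, dict]] = []
        if self.active:
            ev.append((0.0, "resume", {}))
        if self.t_internal is not None:
            ev.append(
                (self.t_internal, "internal_nucleation", {"pos": self.internal_pos})
            )
        if self.t_arrive is not None and self.t_arrive <= self.t_obs:
            ev.append((self.t_arrive, "arrive_end", {}))
        if self.t_rloop_init is not None:
            ev.append(
                (self.t_rloop_init, "rloop_init", {"downstream": self.rloop_downstream})
            )
            t_full = self.t_border_p1
            if t_full is not None and t_full <= self.t_obs:
                ev.append((t_full, "rloop_border_update", {"border": 1}))
        for t in self.ab_times:
            ev.append((float(t), "antibody_bind", {}))
        if self.branch == "runoff" and self.t_rna_loss is not None:
            if self.t_rna_loss <= self.t_obs:
                ev.append((self.t_rna_loss, "rna_dissociate", {}))
        if self.t_digested is not None and self.t_digested <= self.t_obs:
            ev.append((self.t_digested, "rnaseh_digested", {}))
        for t, kind in self.reinit_events:
            ev.append((t, f"reinit_{kind}", {}))
        ev.sort(key=lambda e: (e[0], e[1]))
        return ev

    def replace(self, **kw) -> "StateTrajectory":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
def _sample_binding_times(
    rng: np.random.Generator,
    t_nucleate: float,
    params: KineticParams,
    hybrid_max: float,
    t_end: float,
) -> np.ndarray:
    """Antibody binding times for a hybrid growing at v_ext from t_nucleate.

    Piecewise-constant-rate Poisson sampling: epitope j becomes available
    when the hybrid reaches L_epitope + (j-1)*epitope_spacing; each open,
    unoccupied epitope binds at rate k_ab.
    """
    p = params
    if p.k_ab <= 0 or hybrid_max < p.L_epitope:
        return np.empty(0)
    n_sites = 1 + int((hybrid_max - p.L_epitope) // p.epitope_spacing)
    open_times = t_nucleate + (
        p.L_epitope + p.epitope_spacing * np.arange(n_sites)
    ) / p.v_ext
    times: list[float] = []
    t = open_times[0]
    n_bound = 0
    target = rng.exponential()
    while t < t_end and n_bound < n_sites:
        n_open = int(np.searchsorted(open_times, t, side="right"))
        rate = p.k_ab * (n_open - n_bound)
        t_next_open = open_times[n_open] if n_open < n_sites else math.inf
        if rate <= 0:
            t = t_next_open
            continue
        dt_hit = target / rate
        if t + dt_hit <= min(t_next_open, t_end):
            t += dt_hit
            times.append(t)
            n_bound += 1
            target = rng.exponential()
        else:
            seg = min(t_next_open, t_end) - t
            target -= rate * seg
            t = min(t_next_open, t_end)
    return np.asarray(times)


def simulate_molecule(
    template: TemplateSpec | str,
    params: KineticParams,
    seed: int,
    molecule_id: int = 0,
    force_branch: str | None = None,
) -> StateTrajectory:
    """Simulate one molecule; ``seed`` fixes all randomness.

    ``force_branch`` pins the downstream-end branch (used for conditional
    cohorts such as R-loop-only controls); the branch random draw is still
    consumed so trajectories stay comparable across conditions.
    """
    template = build_template(template)
    p = params
    if force_branch is not None and force_branch not in _BRANCHES:
        raise ValueError(f"force_branch must be one of {_BRANCHES}")
    rng = np.random.default_rng(seed)

    if rng.random() < p.p_inactive:
        return StateTrajectory(
            molecule_id=molecule_id, seed=seed, template=template, params=p,
            active=False, branch=None,
        )

    traj = StateTrajectory(
        molecule_id=molecule_id, seed=seed, template=template, params=p,
        active=True, branch=None,
    )
    run_dist = template.downstream_end - template.stall_site
    t_arr = run_dist / p.k_elong

    # Internal nucleation while elongating (long templates).
    if p.k_nucleate_internal > 0:
        t_nuc = rng.exponential(1.0 / p.k_nucleate_internal)
        if t_nuc < t_arr:
            pos = template.stall_site + p.k_elong * t_nuc
            traj.internal = True
            traj.branch = "rloop"
            traj.t_internal = t_nuc
            traj.internal_pos = pos
            traj.t_arrive = t_nuc + (template.downstream_end - pos) / (
                p.k_elong * p.f_hindrance
            )
            traj.t_rloop_init = t_nuc
            traj.rloop_downstream = pos
            traj.ab_times = _sample_binding_times(
                rng, t_nuc, p, traj.hybrid_max, p.t_obs
            )
            return traj

    traj.t_arrive = t_arr
    u = rng.random()
    cum = np.cumsum(p.p_branch)
    branch = _BRANCHES[int(np.searchsorted(cum, u, side="right"))]
    if force_branch is not None:
        branch = force_branch
    traj.branch = branch

    if branch == "rloop":
        delay = rng.exponential(1.0 / p.k_rloop_init) if p.k_rloop_init > 0 else 0.0
        traj.t_rloop_init = t_arr + delay
        traj.rloop_downstream = float(template.downstream_end)
        traj.ab_times = _sample_binding_times(
            rng, traj.t_rloop_init, p, traj.hybrid_max, p.t_obs
        )
    elif branch == "runoff":
        traj.t_rna_loss = t_arr + rng.exponential(1.0 / p.k_off_rna)
    return traj


def molecule_seed(cohort_seed: int, index: int) -> int:
    """Stable per-molecule seed derived from (cohort seed, molecule index)."""
    ss = np.random.SeedSequence([int(cohort_seed), int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def simulate_cohort(
    template: TemplateSpec | str,
    params: KineticParams,
    n: int,
    seed: int,
    force_branch: str | None = None,
) -> list[StateTrajectory]:
    """Simulate ``n`` molecules with reproducible per-molecule seeds."""
    if n < 1:
        raise ValueError("n must be >= 1")
    template = build_template(template)
    return [
        simulate_molecule(
            template, params, molecule_seed(seed, i), molecule_id=i,
            force_branch=force_branch,
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
def apply_rnaseh(
    traj: StateTrajectory, t_add: float, params: KineticParams | None = None
) -> StateTrajectory:
    """Add RNase H at ``t_add``: an existing hybrid is digested after an
    Exp(k_rnaseh) wait, ending the RNA (Cy3) and antibody signals.

    Molecules without a hybrid at ``t_add`` are returned unchanged.  The
    digestion draw is seeded deterministically from the trajectory seed.
    """
    p = params or traj.params
    if not 0 <= t_add <= traj.t_obs:
        raise ValueError("t_add must lie within [0, t_obs]")
    has_hybrid = (
        traj.t_rloop_init is not None
        and traj.t_rloop_init <= t_add < traj.t_hybrid_end
        and bool(traj.rna_present(t_add))
    )
    if not has_hybrid:
        return traj
    rng = np.random.default_rng(np.random.SeedSequence([traj.seed, 0xD1D]))
    wait = 0.0 if math.isinf(p.k_rnaseh) else (
        rng.exponential(1.0 / p.k_rnaseh) if p.k_rnaseh > 0 else math.inf
    )
    t_dig = t_add + wait
    if math.isinf(t_dig):
        return traj
    return traj.replace(
        t_digested=t_dig,
        t_hybrid_end=min(traj.t_hybrid_end, t_dig),
        t_rna_loss=min(traj.t_rna_loss, t_dig)
        if traj.t_rna_loss is not None else t_dig,
        ab_times=traj.ab_times[traj.ab_times < t_dig],
    )


def simulate_reinitiation(
    traj: StateTrajectory, params: KineticParams | None = None, t_add: float = 0.0
) -> StateTrajectory:
    """Apply next-round initiation pressure from ``t_add`` on.

    Initiation attempts arrive at rate ``k_reinit``.  An attempt succeeds
    iff no R-loop covers the promoter/+1 region at that moment (scenario I:
    the hybrid is unwound and the Cy3-RNA departs); otherwise it is logged
    as blocked (scenario II) and pressure continues.
    """
    p = params or traj.params
    if p.k_reinit <= 0:
        return traj
    rng = np.random.default_rng(np.random.SeedSequence([traj.seed, 0x4E17]))
    out = traj
    events: list[tuple[float, str]] = []
    t = t_add
    while True:
        t += rng.exponential(1.0 / p.k_reinit)
        if t >= traj.t_obs:
            break
        border = out.rloop_upstream_border(t)
        covered = (not math.isnan(border)) and border <= 1.0
        if covered:
            events.append((t, "blocked"))
            continue
        events.append((t, "success"))
        out = out.replace(
            t_rna_loss=min(t, out.t_rna_loss)
            if out.t_rna_loss is not None else t,
            t_hybrid_end=min(out.t_hybrid_end, t),
            ab_times=out.ab_times[out.ab_times < t],
        )
        break
    return out.replace(reinit_events=traj.reinit_events + tuple(events))
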