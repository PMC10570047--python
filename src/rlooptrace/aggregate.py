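"""Cohort-level statistics: event fractions, timing means, high-FRET
population curves, extension-speed estimation, overhang-dependence tables
and the next-round blocking/RNase-H curves.

Fractions carry Wilson 95% intervals (preferred over Wald for the small
counts typical of single-molecule cohorts); timing-derived quantities use
a seeded molecule-level bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classify import classify_cohort, compute_fret_series, detect_high_fret, detect_step_onset
from .params import ClassifyConfig, KineticParams, OpticsParams
from .photophysics import Trace, render_cohort, render_trace
from .simulate import (
    StateTrajectory,
    apply_rnaseh,
    simulate_cohort,
    simulate_reinitiation,
)
from .templates import build_template

__all__ = [
    "CohortSummary",
    "wilson_interval",
    "summarize_cohort",
    "highfret_population_curve",
    "estimate_extension_speed",
    "overhang_dependence_table",
    "blocked_fraction_curve",
    "run_blocking_experiment",
    "measure_scheme_timings",
    "timing_order_fractions",
    "survival_half_life",
]

_CLASSES = ("rloop", "runoff", "retention")


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial fraction."""
    if n <= 0:
        raise ValueError("n must be > 0")
    z = stats.norm.ppf(0.5 + conf / 2.0)
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(center - half, 0.0), min(center + half, 1.0))


@dataclass
class CohortSummary:
    """Figure-level summary of one classified cohort."""

    template: str
    n_total: int
    n_active: int
    n_by_class: dict[str, int]
    fractions: dict[str, float]
    intervals: dict[str, tuple[float, float]]
    mean_t_ab_onset: float | None = None
    se_t_ab_onset: float | None = None
    mean_t_cy3_loss: float | None = None
    se_t_cy3_loss: float | None = None
    mean_t_run: float | None = None
    se_t_run: float | None = None
    mean_highfret_lag: float | None = None
    se_highfret_lag: float | None = None
    n_censored: int = 0
    curves: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.n_by_class.values()) != self.n_active:
            raise ValueError("class counts must sum to n_active")
        if self.n_active > self.n_total:
            raise ValueError("n_active cannot exceed n_total")
        for f in self.fractions.values():
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")

    @property
    def rloop_efficiency(self) -> float:
        return self.fractions["rloop"]


def _mean_se(x: pd.Series) -> tuple[float | None, float | None]:
    x = x.dropna()
    if len(x) == 0:
        return None, None
    m = float(x.mean())
    se = float(x.std(ddof=1) / math.sqrt(len(x))) if len(x) > 1 else None
    return m, se


def summarize_cohort(calls: pd.DataFrame, template: str = "") -> CohortSummary:
    """Exact counts, Wilson 95% intervals and timing means for one cohort."""
    if len(calls) == 0:
        raise ValueError("empty calls table")
    active = calls[calls["active"]]
    n_active = len(active)
    if n_active == 0:
        raise ValueError("no active molecules in cohort")
    n_by_class = {c: int((active["event_class"] == c).sum()) for c in _CLASSES}
    fractions = {c: n_by_class[c] / n_active for c in _CLASSES}
    intervals = {c: wilson_interval(n_by_class[c], n_active) for c in _CLASSES}

    rl = active[active["event_class"] == "rloop"]
    ro = active[active["event_class"] == "runoff"]
    m_ab, se_ab = _mean_se(rl["t_ab_onset"]) if len(rl) else (None, None)
    m_cy, se_cy = _mean_se(ro["t_cy3_loss"]) if len(ro) else (None, None)
    m_run, se_run = _mean_se(active["t_pife_onset"])
    lag = (rl["t_highfret_entry"] - rl["t_ab_onset"]) if len(rl) else pd.Series(dtype=float)
    m_hf, se_hf = _mean_se(lag)
    n_censored = int(
        calls["qc_flags"].fillna("").str.contains("censored").sum()
    ) if "qc_flags" in calls else 0
    return CohortSummary(
        template=template,
        n_total=len(calls),
        n_active=n_active,
        n_by_class=n_by_class,
        fractions=fractions,
        intervals=intervals,
        mean_t_ab_onset=m_ab, se_t_ab_onset=se_ab,
        mean_t_cy3_loss=m_cy, se_t_cy3_loss=se_cy,
        mean_t_run=m_run, se_t_run=se_run,
        mean_highfret_lag=m_hf, se_highfret_lag=se_hf,
        n_censored=n_censored,
    )


def merge_summaries(a: CohortSummary, b: CohortSummary) -> CohortSummary:
    """Pool two disjoint cohorts of the same template (counts are additive)."""
    n_by_class = {c: a.n_by_class[c] + b.n_by_class[c] for c in _CLASSES}
    n_active = a.n_active + b.n_active
    return CohortSummary(
        template=a.template,
        n_total=a.n_total + b.n_total,
        n_active=n_active,
        n_by_class=n_by_class,
        fractions={c: n_by_class[c] / n_active for c in _CLASSES},
        intervals={c: wilson_interval(n_by_class[c], n_active) for c in _CLASSES},
    )


# ---------------------------------------------------------------------------
def highfret_population_curve(
    traces: list[Trace],
    grid: np.ndarray,
    config: ClassifyConfig | None = None,
    calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fraction of surviving molecules inside a sustained E>threshold
    interval at each grid time, with a Mann-Kendall trend statistic.

    A molecule "survives" at t while its donor+acceptor total is above the
    validity threshold (i.e. Cy3 alive); the fraction is taken over
    survivors.  If a ``calls`` table is supplied, inactive molecules are
    excluded (their stalled baseline sits just below the threshold and
    does not report R-loop extension).
    """
    cfg = config or ClassifyConfig()
    if calls is not None:
        keep = set(calls[calls["active"]]["molecule_id"])
        traces = [tr for tr in traces if tr.molecule_id in keep]
    grid = np.asarray(grid, dtype=float)
    in_high = np.zeros((len(traces), len(grid)), dtype=bool)
    alive = np.zeros_like(in_high)
    for i, tr in enumerate(traces):
        E = compute_fret_series(tr, cfg.gamma, cfg.background, cfg.min_total)
        from .classify import _median_filter  # shared smoothing

        x = _median_filter(E, cfg.smoothing_width)
        defined = ~np.isnan(x)
        high = (x > cfg.high_fret_threshold) & defined
        # sustain requirement: min_dwell consecutive frames
        w = cfg.min_dwell_frames
        runs = np.convolve(high.astype(int), np.ones(w, dtype=int), "valid") == w
        sustained = np.zeros_like(high)
        for off in range(w):
            sustained[off : off + len(runs)] |= runs
        idx = np.searchsorted(tr.t, grid, side="right") - 1
        idx = np.clip(idx, 0, len(tr.t) - 1)
        in_high[i] = sustained[idx]
        alive[i] = defined[idx]
    n_alive = alive.sum(axis=0)
    n_total = max(len(traces), 1)
    # primary fraction over the (fixed) active cohort: molecules that lost
    # their donor cannot be in a high-FRET state and count as not-high;
    # the survivor-normalized fraction is reported alongside
    frac = in_high.sum(axis=0) / n_total
    with np.errstate(invalid="ignore"):
        frac_surv = np.where(n_alive > 0, in_high.sum(axis=0) / n_alive, np.nan)
    out = pd.DataFrame({"t": grid, "high_fret_fraction": frac,
                        "high_fret_fraction_surviving": frac_surv,
                        "n_surviving": n_alive})
    ok = ~np.isnan(frac)
    if ok.sum() >= 3 and np.ptp(frac[ok]) > 0:
        tau, p = stats.kendalltau(grid[ok], frac[ok])
        out.attrs["mann_kendall_tau"] = float(tau)
        out.attrs["mann_kendall_p"] = float(p)
    return out


# ---------------------------------------------------------------------------
def estimate_extension_speed(
    points: list[tuple[float, float]] | None = None,
    per_molecule: pd.DataFrame | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """R-loop upstream-extension speed from (template position, time) data.

    ``points`` are (position_bp, mean_time_s) pairs, times measured
    relative to the antibody onset; the slope of position vs. time is
    sign-flipped so an upstream-moving border reports a positive speed.
    Alternatively ``per_molecule`` is a tidy frame with columns
    ``molecule``, ``position``, ``time``; the fit then runs on per-position
    means with a molecule-level bootstrap interval.

    Returns ``{"speed", "interval", "pairwise_range", "n"}``.
    """
    if per_molecule is not None:
        df = per_molecule.dropna(subset=["time"])
        pts = df.groupby("position")["time"].mean()
        points = list(zip(pts.index.to_numpy(float), pts.to_numpy(float)))
    if points is None or len(points) < 2:
        raise ValueError("need at least two (position, time) points")
    pos = np.asarray([p for p, _ in points], dtype=float)
    tt = np.asarray([t for _, t in points], dtype=float)
    if len(np.unique(pos)) < 2:
        raise ValueError("positions must be distinct")
    if np.ptp(tt) == 0:
        raise ValueError("degenerate times: no spread to fit a speed")
    slope = np.polyfit(tt, pos, 1)[0]
    speed = -float(slope)
    pairwise = [
        -(pos[j] - pos[i]) / (tt[j] - tt[i])
        for i in range(len(pos))
        for j in range(i + 1, len(pos))
        if tt[j] != tt[i]
    ]
    out = {
        "speed": speed,
        "pairwise_range": (min(pairwise), max(pairwise)) if pairwise else None,
        "n": len(pos),
        "interval": None,
    }
    if per_molecule is not None and n_boot > 0:
        rng = np.random.default_rng(seed)
        mols = df["molecule"].unique()
        boots = []
        by_mol = {m: g for m, g in df.groupby("molecule")}
        for _ in range(n_boot):
            pick = rng.choice(mols, size=len(mols), replace=True)
            sub = pd.concat([by_mol[m] for m in pick])
            means = sub.groupby("position")["time"].mean()
            if len(means) >= 2 and np.ptp(means.to_numpy()) > 0:
                boots.append(
                    -np.polyfit(means.to_numpy(float),
                                means.index.to_numpy(float), 1)[0]
                )
        if boots:
            out["interval"] = tuple(np.percentile(boots, [2.5, 97.5]))
    return out


def overhang_dependence_table(
    summaries: dict[tuple[str, int], CohortSummary]
    | list[tuple[tuple[str, int], CohortSummary]]
) -> pd.DataFrame:
    """Ordered efficiency table keyed by (polarity, overhang length).

    ``summaries`` is a mapping or a ((polarity, length), summary) pair
    list; rows are sorted by polarity then length, and a Spearman trend of
    efficiency vs. length is attached per polarity (``.attrs``).
    """
    items = list(summaries.items()) if isinstance(summaries, dict) \
        else list(summaries)
    keys = [k for k, _ in items]
    if len(keys) != len(set(keys)):
        raise ValueError("duplicate (polarity, length) keys")
    rows = []
    for (pol, length), s in items:
        lo, hi = s.intervals["rloop"]
        rows.append(
            dict(polarity=pol, overhang_len=length,
                 rloop_efficiency=s.fractions["rloop"],
                 ci_low=lo, ci_high=hi, n_active=s.n_active)
        )
    df = pd.DataFrame(rows).sort_values(
        ["polarity", "overhang_len"]).reset_index(drop=True)
    trends = {}
    for pol, sub in df.groupby("polarity"):
        if len(sub) >= 3:
            rho, p = stats.spearmanr(sub["overhang_len"], sub["rloop_efficiency"])
            trends[pol] = {"spearman_rho": float(rho), "p_value": float(p)}
    df.attrs["trends"] = trends
    return df


# ---------------------------------------------------------------------------
def run_blocking_experiment(
    n: int,
    seed: int,
    t_add: float = 180.0,
    arms: tuple[str, ...] = ("reinit", "control", "rnaseh"),
    template: str = "DT3",
    params: KineticParams | None = None,
    optics: OpticsParams | None = None,
    config: ClassifyConfig | None = None,
    detected: bool = True,
) -> pd.DataFrame:
    """Next-round blocking experiment on fully extended R-loops.

    Simulates ``n`` R-loop-branch molecules, keeps those whose R-loop has
    reached +1 by ``t_add`` with the RNA still present (the high-FRET
    population that is challenged), then applies each arm:

    * ``reinit``  - holoenzyme + NTPs: initiation pressure at ``k_reinit``;
    * ``control`` - holoenzyme only (no pressure);
    * ``rnaseh``  - RNase H digestion of the hybrid.

    Returns a tidy frame (arm, molecule, t_loss) where ``t_loss`` is the
    detected (or ground-truth) Cy3 loss time, NaN if retained to t_obs.
    """
    from .calibration import preset_kinetics

    tpl = build_template(template)
    p = params or preset_kinetics(template)
    p = p.replace(p_inactive=0.0, t_obs=t_add + 600.0)
    optics = optics or OpticsParams()
    cfg = config or ClassifyConfig.from_optics(optics)
    base = simulate_cohort(tpl, p, n, seed, force_branch="rloop")
    full = [
        tr for tr in base
        if tr.t_border_p1 is not None and tr.t_border_p1 <= t_add
        and bool(tr.rna_present(t_add))
    ]
    rows = []
    for arm in arms:
        for tr in full:
            if arm == "reinit":
                mod = simulate_reinitiation(tr, p, t_add)
            elif arm == "control":
                mod = tr
            elif arm == "rnaseh":
                mod = apply_rnaseh(tr, t_add, p)
            else:
                raise ValueError(f"unknown arm {arm!r}")
            if detected:
                trace = render_trace(mod, optics, seed=mod.seed ^ 0xA5A5)
                t_loss = detect_step_onset(
                    trace.channel("donor_em_green_ex")
                    + trace.channel("acceptor_em_green_ex"),
                    "down", cfg.cy3_min_delta, cfg.min_dwell_frames,
                    cfg.smoothing_width,
                    baseline_frames=max(int(np.sum(trace.t < 0)), 1),
                    t=trace.t,
                )
            else:
                t_loss = mod.t_rna_loss
                if t_loss is not None and t_loss > p.t_obs:
                    t_loss = None
            rows.append(dict(arm=arm, molecule=tr.molecule_id,
                             t_loss=np.nan if t_loss is None else t_loss))
    return pd.DataFrame(rows)


def blocked_fraction_curve(
    losses: pd.DataFrame, grid: np.ndarray, t_add: float = 0.0
) -> pd.DataFrame:
    """Cy3-retaining fraction vs. time per experimental arm.

    ``losses`` holds (arm, molecule, t_loss) with NaN for retained
    molecules; the fraction at grid time g is P(t_loss > g).
    """
    if "arm" not in losses.columns:
        raise ValueError("losses frame must carry an 'arm' column")
    grid = np.asarray(grid, dtype=float)
    out = {"t": grid}
    for arm, sub in losses.groupby("arm"):
        tl = sub["t_loss"].to_numpy(float)
        out[str(arm)] = [
            float(np.mean(np.isnan(tl) | (tl > g))) for g in grid
        ]
    return pd.DataFrame(out)


def survival_half_life(curve: pd.DataFrame, arm: str, t_add: float = 0.0) -> float:
    """Time after ``t_add`` at which an arm's retaining fraction crosses 1/2
    (linear interpolation)."""
    t = curve["t"].to_numpy(float)
    f = curve[arm].to_numpy(float)
    below = np.nonzero(f <= 0.5)[0]
    if below.size == 0:
        raise ValueError(f"arm {arm!r} never falls below 1/2")
    i = below[0]
    if i == 0:
        return float(t[0] - t_add)
    t_half = t[i - 1] + (0.5 - f[i - 1]) * (t[i] - t[i - 1]) / (f[i] - f[i - 1])
    return float(t_half - t_add)


# ---------------------------------------------------------------------------
def measure_scheme_timings(
    trajs: list[StateTrajectory],
    optics: OpticsParams | None = None,
    config: ClassifyConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Detected landmark times for each molecule under all three labeling
    schemes rendered from the same ground truth.

    Columns: ``t_drop`` (scheme-I downstream FRET drop), ``t_ab`` (antibody
    onset), ``t_mid`` (scheme-II mid-template FRET rise), ``t_p1``
    (scheme-III high-FRET entry).  Only R-loop-forming molecules yield a
    full row; missing detections are NaN.
    """
    optics = optics or OpticsParams()
    cfg = config or ClassifyConfig.from_optics(optics)
    tpl_i = build_template("DT3-I")
    tpl_ii = build_template("DT3-II")
    tpl_iii = build_template("DT3-III")
    rows = []
    for i, traj in enumerate(trajs):
        ss = int(np.random.SeedSequence([int(seed), i]).generate_state(
            1, dtype=np.uint32)[0])
        tr1 = render_trace(traj, optics, ss, template=tpl_i)
        tr2 = render_trace(traj, optics, ss ^ 0x1, template=tpl_ii)
        tr3 = render_trace(traj, optics, ss ^ 0x2, template=tpl_iii)
        nb = max(int(np.sum(tr1.t < 0)), 1)
        E1 = compute_fret_series(tr1, cfg.gamma, cfg.background, cfg.min_total)
        t_drop = detect_step_onset(
            E1, "down", cfg.fret_min_delta, cfg.min_dwell_frames,
            cfg.smoothing_width, baseline_frames=nb, t=tr1.t,
        )
        t_ab = detect_step_onset(
            tr3.channel("ab_em_blue_ex"), "up", cfg.ab_min_delta,
            cfg.min_dwell_frames, cfg.smoothing_width, baseline_frames=nb,
            t=tr3.t,
        )
        E2 = compute_fret_series(tr2, cfg.gamma, cfg.background, cfg.min_total)
        t_mid = detect_step_onset(
            E2, "up", cfg.fret_min_delta, cfg.min_dwell_frames,
            cfg.smoothing_width, baseline_frames=nb, t=tr2.t,
        )
        E3 = compute_fret_series(tr3, cfg.gamma, cfg.background, cfg.min_total)
        entries = detect_high_fret(
            E3, cfg.high_fret_threshold, cfg.min_dwell_frames,
            cfg.smoothing_width, t=tr3.t,
        )
        # the stalled baseline sits just below threshold; only entries
        # after NTP injection report the border reaching +1
        entries = entries[entries >= 0.0]
        t_p1 = float(entries[0]) if entries.size else np.nan
        rows.append(dict(
            molecule=traj.molecule_id,
            is_rloop=traj.branch == "rloop",
            t_drop=np.nan if t_drop is None else t_drop,
            t_ab=np.nan if t_ab is None else t_ab,
            t_mid=np.nan if t_mid is None else t_mid,
            t_p1=t_p1,
        ))
    return pd.DataFrame(rows)


def timing_order_fractions(timings: pd.DataFrame) -> dict[str, float]:
    """Per-molecule ordering fractions of the four R-loop landmarks.

    Keys: ``drop_before_ab``, ``ab_before_mid``, ``mid_before_p1``,
    ``full_chain`` (all three in order); fractions are over R-loop
    molecules with all required detections present.
    """
    df = timings[timings["is_rloop"]].dropna(subset=["t_drop", "t_ab",
                                                     "t_mid", "t_p1"])
    if len(df) == 0:
        raise ValueError("no fully detected R-loop molecules")
    drop_ab = df["t_drop"] < df["t_ab"]
    ab_mid = df["t_ab"] < df["t_mid"]
    mid_p1 = df["t_mid"] < df["t_p1"]
    return {
        "n": int(len(df)),
        "drop_before_ab": float(drop_ab.mean()),
        "ab_before_mid": float(ab_mid.mean()),
        "mid_before_p1": float(mid_p1.mean()),
        "full_chain": float((drop_ab & ab_mid & mid_p1).mean()),
    }
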