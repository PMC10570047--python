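import numpy as np
import pandas as pd
import pytest

import rlooptrace as rl
from rlooptrace.photophysics import Trace


def _toy_trace(D, A, red=None, ab=None, dt=0.5):
    n = len(D)
    z = np.full(n, 100.0)
    return Trace(
        molecule_id=0, frame_dt=dt, t=np.arange(n) * dt,
        channels={
            "donor_em_green_ex": np.asarray(D, float),
            "acceptor_em_green_ex": np.asarray(A, float),
            "acceptor_em_red_ex": z if red is None else np.asarray(red, float),
            "ab_em_blue_ex": z if ab is None else np.asarray(ab, float),
        },
    )


def test_fret_series_reference_values():
    tr = _toy_trace([600.0] * 10, [600.0] * 10)
    E = rl.compute_fret_series(tr, gamma=1.0, background=100.0, min_total=200.0)
    assert np.allclose(E, 0.5)
    tr0 = _toy_trace([600.0] * 10, [100.0] * 10)
    assert np.allclose(rl.compute_fret_series(tr0, 1.0, 100.0, 200.0), 0.0)
    dark = _toy_trace([100.0] * 10, [100.0] * 10)
    with pytest.raises(ValueError):
        rl.compute_fret_series(dark, 1.0, 100.0, 200.0)


def test_step_onset_noiseless_and_degenerate():
    x = np.concatenate([np.zeros(50), np.ones(100)])
    t = np.arange(150) * 0.5
    assert rl.detect_step_onset(x, "up", 0.5, t=t) == pytest.approx(25.0)
    assert rl.detect_step_onset(np.zeros(100), "up", 0.5) is None
    assert rl.detect_step_onset(-x, "down", 0.5, t=t) == pytest.approx(25.0)
    with pytest.raises(ValueError):
        rl.detect_step_onset(x, "up", 0.5, min_dwell_frames=0)
    with pytest.raises(ValueError):
        rl.detect_step_onset(x, "sideways", 0.5)


def _lsq_changepoint(x):
    """Exhaustive two-segment least-squares split (independent oracle)."""
    n = len(x)
    best, best_cost = None, np.inf
    csum = np.cumsum(x)
    csum2 = np.cumsum(x * x)
    for k in range(2, n - 2):
        s1, s2 = csum[k - 1], csum[-1] - csum[k - 1]
        q1, q2 = csum2[k - 1], csum2[-1] - csum2[k - 1]
        cost = (q1 - s1 * s1 / k) + (q2 - s2 * s2 / (n - k))
        if cost < best_cost:
            best, best_cost = k, cost
    return best


def test_detector_matches_exhaustive_changepoint_oracle():
    # 1000 noisy steps at SNR 3, known change frames
    rng = np.random.default_rng(2024)
    n, ok_det, ok_oracle = 1000, 0, 0
    for _ in range(n):
        k = int(rng.integers(40, 160))
        x = np.concatenate([np.zeros(k), np.ones(200 - k)])
        x += rng.normal(0, 1 / 3, 200)
        det = rl.detect_step_onset(x, "up", 0.5, baseline_frames=20)
        if det is not None and abs(det - k) <= 2:
            ok_det += 1
        if abs(_lsq_changepoint(x) - k) <= 2:
            ok_oracle += 1
    assert ok_det / n >= 0.95
    assert ok_oracle / n >= 0.95


def test_classify_active_resume_and_never_resuming(optics, cfg):
    kp = rl.preset_kinetics("DT1", p_branch=(0, 1, 0), p_inactive=0.0)
    traj = rl.simulate_molecule("DT1", kp, seed=3)
    tr = rl.render_trace(traj, optics, seed=4)
    active, t_resume = rl.classify_active(tr, cfg)
    assert active and abs(t_resume) <= 2 * optics.frame_dt

    frozen = rl.simulate_molecule(
        "DT1", rl.preset_kinetics("DT1", p_inactive=1 - 1e-9), seed=5)
    tr2 = rl.render_trace(frozen, optics, seed=6)
    assert rl.classify_active(tr2, cfg) == (False, None)


_PRESETS = ["DT1", "DT2", "DT3", "DT7", "DT3-I", "DT3-II", "DT8"]


@pytest.mark.parametrize("preset", _PRESETS)
def test_noiseless_classification_equals_ground_truth(
    preset, noiseless, cfg_noiseless
):
    """On noise-free renders every EventCall field matches the trajectory
    within one frame interval, for every preset template."""
    kp = rl.preset_kinetics(preset, p_inactive=0.0)
    trajs = rl.simulate_cohort(preset, kp, 40, seed=700 + len(preset))
    traces = rl.render_cohort(trajs, noiseless, seed=800)
    calls = [rl.classify_event(tr, cfg_noiseless) for tr in traces]
    dt = noiseless.frame_dt
    scheme = rl.build_template(preset).scheme
    cy3_on_rna = scheme in ("III", "end")
    for traj, call in zip(trajs, calls):
        truth_ab = traj.ab_times[0] if len(traj.ab_times) else None
        if truth_ab is not None and truth_ab < traj.t_obs - 5 * dt:
            assert call.event_class == "rloop"
            assert abs(call.t_ab_onset - truth_ab) <= dt
        elif traj.branch == "runoff":
            if cy3_on_rna:
                if traj.t_rna_loss < traj.t_obs - 5 * dt:
                    assert call.event_class == "runoff"
                    assert abs(call.t_cy3_loss - traj.t_rna_loss) <= dt
            else:
                # Cy3 sits on DNA: dissociation is invisible, read as retention
                assert call.event_class == "retention"
        elif traj.branch == "retention":
            assert call.event_class == "retention"
        # high-FRET entry equals the border-reaches-+1 time (scheme III)
        if (
            scheme == "III" and call.t_highfret_entry is not None
            and traj.t_border_p1 is not None
        ):
            assert abs(call.t_highfret_entry - traj.t_border_p1) <= dt
        # antibody step count matches the bound count
        n_truth = len(traj.ab_times[traj.ab_times < traj.t_obs - 5 * dt])
        assert abs(call.n_ab_steps - n_truth) <= 1


def test_taxonomy_exhaustive_and_exclusive(dt1_calls):
    _, calls = dt1_calls
    active = calls[calls["active"]]
    assert set(active["event_class"]) <= {"rloop", "runoff", "retention"}
    fr = active["event_class"].value_counts(normalize=True)
    assert fr.sum() == pytest.approx(1.0)
    # invariant: class tied to which onsets are set
    rl_rows = active[active["event_class"] == "rloop"]
    assert rl_rows["t_ab_onset"].notna().all()
    ro = active[active["event_class"] == "runoff"]
    assert ro["t_cy3_loss"].notna().all() and ro["t_ab_onset"].isna().all()
    ret = active[active["event_class"] == "retention"]
    assert ret["t_ab_onset"].isna().all()


def test_raising_ab_threshold_never_creates_rloop_calls(optics):
    kp = rl.preset_kinetics("DT1")
    trajs = rl.simulate_cohort("DT1", kp, 150, seed=31)
    traces = rl.render_cohort(trajs, optics, seed=32)
    lo = rl.ClassifyConfig.from_optics(optics)
    hi = lo.replace(ab_min_delta=2.2 * lo.ab_min_delta)
    calls_lo = rl.classify_cohort(traces, lo)
    calls_hi = rl.classify_cohort(traces, hi)
    set_lo = set(calls_lo[calls_lo.event_class == "rloop"].molecule_id)
    set_hi = set(calls_hi[calls_hi.event_class == "rloop"].molecule_id)
    assert set_hi <= set_lo


def test_high_fret_strictly_above_threshold():
    E = np.full(200, 0.69)
    assert rl.detect_high_fret(E, threshold=0.7).size == 0
    E2 = np.concatenate([np.full(100, 0.2), np.full(100, 0.75)])
    entries = rl.detect_high_fret(E2, threshold=0.7)
    assert entries.size == 1 and entries[0] == 100


def test_pife_onset_none_without_pife(noiseless, cfg_noiseless):
    kp = rl.preset_kinetics("DT3", p_branch=(0, 0, 1), p_inactive=0.0)
    traj = rl.simulate_molecule("DT3", kp, seed=7, force_branch="retention")
    tr = rl.render_trace(traj, noiseless, seed=8)
    assert rl.detect_pife_onset(tr, cfg_noiseless) is None


def test_count_antibody_steps_flat_is_zero(cfg):
    tr = _toy_trace([600] * 50, [600] * 50)
    assert rl.count_antibody_steps(tr, cfg).size == 0


def test_misclassification_rate_under_default_noise(dt1_calls):
    trajs, calls = dt1_calls
    truth = pd.Series(
        [t.branch if t.active else "inactive" for t in trajs]
    )
    # schemes with Cy3 on RNA: truth classes map one-to-one
    agree = (truth == calls["event_class"]).mean()
    assert agree >= 0.98
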