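import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import rlooptrace as rl
from rlooptrace.calibration import K_ELONG


def _fast_init(kp, **kw):
    """Variant with a negligible nucleation delay (deterministic limit)."""
    return kp.replace(k_rloop_init=1e9, **kw)


def test_deterministic_extension_reaches_plus1():
    # with an immediate nucleation the border travels (D-1)/v_ext
    kp = _fast_init(rl.preset_kinetics("DT1", p_branch=(1, 0, 0),
                                       p_inactive=0.0, v_ext=2.0))
    tr = rl.simulate_molecule("DT1", kp, seed=1)
    assert tr.branch == "rloop"
    assert tr.t_border_p1 - tr.t_rloop_init == pytest.approx(100 / 2.0)
    assert tr.t_rloop_init == pytest.approx(tr.t_arrive, abs=1e-6)


def test_runoff_dissociation_mean_matches_configured_rate():
    # sample mean of Exp(1/15) over 10k seeds
    kp = rl.preset_kinetics("DT1", p_branch=(0, 1, 0), p_inactive=0.0,
                            k_off_rna=1.0 / 15.0)
    trajs = rl.simulate_cohort("DT1", kp, 10_000, seed=42)
    waits = np.array([t.t_rna_loss - t.t_arrive for t in trajs])
    assert waits.mean() == pytest.approx(15.0, abs=0.5)
    # and the full waiting-time distribution is the stated exponential
    ks = stats.kstest(waits, "expon", args=(0, 15.0))
    assert ks.pvalue > 0.01


def test_dt8_arrival_time_is_distance_over_speed():
    kp = rl.preset_kinetics("DT8", k_nucleate_internal=0.0, p_inactive=0.0)
    tr = rl.simulate_molecule("DT8", kp, seed=3)
    assert kp.k_elong == pytest.approx(206.2264, abs=1e-3)
    assert tr.t_arrive == pytest.approx((1103 - 10) / K_ELONG)
    assert tr.t_arrive == pytest.approx(5.3, abs=0.01)


def test_cohort_determinism_and_size():
    kp = rl.preset_kinetics("DT1")
    a = rl.simulate_cohort("DT1", kp, 50, seed=7)
    b = rl.simulate_cohort("DT1", kp, 50, seed=7)
    for x, y in zip(a, b):
        assert x.events == y.events
        assert np.array_equal(x.ab_times, y.ab_times)
    assert len(rl.simulate_cohort("DT1", kp, 1, seed=0)) == 1
    with pytest.raises(ValueError):
        rl.simulate_cohort("DT1", kp, 0, seed=0)


def test_branch_fractions_recover_within_binomial_error():
    kp = rl.preset_kinetics("DT1", p_branch=(0.73, 0.25, 0.02), p_inactive=0.0)
    trajs = rl.simulate_cohort("DT1", kp, 2000, seed=9)
    counts = {b: sum(t.branch == b for t in trajs)
              for b in ("rloop", "runoff", "retention")}
    assert sum(counts.values()) == 2000  # conservation
    sd = math.sqrt(0.73 * 0.27 * 2000)
    assert abs(counts["rloop"] - 1460) <= 3 * sd


def test_border_monotone_and_bounded():
    kp = _fast_init(rl.preset_kinetics("DT1", p_branch=(1, 0, 0), p_inactive=0.0))
    tr = rl.simulate_molecule("DT1", kp, seed=5)
    t = np.linspace(tr.t_rloop_init, 600, 500)
    border = tr.rloop_upstream_border(t)
    assert np.all(np.diff(border) <= 1e-9)
    assert border.min() >= 1.0
    # downstream border constant once set
    assert tr.rloop_downstream == 101.0


def test_first_antibody_binding_gated_by_epitope_length():
    kp = rl.preset_kinetics("DT1", p_branch=(1, 0, 0), p_inactive=0.0)
    trajs = rl.simulate_cohort("DT1", kp, 400, seed=11)
    for tr in trajs:
        if len(tr.ab_times):
            assert tr.ab_times[0] >= tr.t_eligible - 1e-9
            assert np.all(np.diff(tr.ab_times) > 0)


def test_antibody_wait_distribution_single_epitope():
    # with one epitope (huge spacing) the post-eligibility wait is Exp(k_ab)
    kp = rl.preset_kinetics(
        "DT1", p_branch=(1, 0, 0), p_inactive=0.0, epitope_spacing=1e9,
    )
    trajs = rl.simulate_cohort("DT1", kp, 4000, seed=13)
    waits = np.array([t.ab_times[0] - t.t_eligible
                      for t in trajs if len(t.ab_times)])
    assert len(waits) > 3500
    ks = stats.kstest(waits, "expon", args=(0, 1.0 / kp.k_ab))
    assert ks.pvalue > 0.01


def test_rnaseh_no_hybrid_is_noop_and_fast_digestion_is_immediate():
    kp = rl.preset_kinetics("DT1", p_branch=(0, 0, 1), p_inactive=0.0)
    tr = rl.simulate_molecule("DT1", kp, seed=1)
    assert rl.apply_rnaseh(tr, 100.0, kp) is tr
    kp2 = _fast_init(rl.preset_kinetics("DT1", p_branch=(1, 0, 0),
                                        p_inactive=0.0, k_rnaseh=math.inf))
    tr2 = rl.simulate_molecule("DT1", kp2, seed=2)
    dig = rl.apply_rnaseh(tr2, 100.0, kp2)
    assert not dig.rna_present(100.0 + 1e-6)
    assert dig.n_antibody(100.0 + 1e-6) == 0


def test_rnaseh_survival_is_exponential():
    kp = _fast_init(rl.preset_kinetics("DT1", p_branch=(1, 0, 0),
                                       p_inactive=0.0, k_rnaseh=0.05))
    trajs = rl.simulate_cohort("DT1", kp, 2000, seed=17)
    t_add = 150.0
    dig = [rl.apply_rnaseh(t, t_add, kp) for t in trajs]
    waits = np.array([d.t_digested - t_add for d in dig])
    ks = stats.kstest(waits, "expon", args=(0, 20.0))
    assert ks.pvalue > 0.01


def test_reinitiation_blocked_by_full_rloop_and_succeeds_without():
    kp = _fast_init(rl.preset_kinetics("DT3", p_branch=(1, 0, 0),
                                       p_inactive=0.0, k_reinit=0.05))
    tr = rl.simulate_molecule("DT3", kp, seed=3)
    t_add = tr.t_border_p1 + 10.0
    out = rl.simulate_reinitiation(tr, kp, t_add)
    kinds = {k for _, k in out.reinit_events}
    assert kinds == {"blocked"}
    assert out.rna_present(599.0)

    kp2 = kp.replace(p_branch=(0, 0, 1))
    tr2 = rl.simulate_molecule("DT3", kp2, seed=4, force_branch="retention")
    out2 = rl.simulate_reinitiation(tr2, kp2, 10.0)
    succ = [t for t, k in out2.reinit_events if k == "success"]
    assert len(succ) == 1
    assert out2.t_rna_loss == pytest.approx(succ[0])

    kp0 = kp.replace(k_reinit=0.0)
    assert rl.simulate_reinitiation(tr, kp0, 10.0) is tr


def test_internal_nucleation_slows_arrival():
    kp = rl.preset_kinetics("DT8")
    trajs = rl.simulate_cohort("DT8", kp, 1500, seed=19)
    internal = [t for t in trajs if t.internal]
    assert internal, "expect some internal formers"
    for t in internal:
        assert t.t_arrive > 5.31  # hindered arrival later than unhindered
        assert t.rloop_downstream == pytest.approx(t.internal_pos)
    # non-internal molecules arrive on schedule
    normal = next(t for t in trajs if t.active and not t.internal)
    assert normal.t_arrive == pytest.approx(5.3, abs=0.01)


@given(seed=st.integers(0, 2**20), v_ext=st.floats(0.5, 10.0),
       mean_delay=st.floats(1.0, 100.0))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_trajectory_invariants_hold_across_parameters(seed, v_ext, mean_delay):
    kp = rl.preset_kinetics(
        "DT1", p_branch=(0.6, 0.3, 0.1), v_ext=v_ext,
        k_rloop_init=1.0 / mean_delay, p_inactive=0.1,
    )
    tr = rl.simulate_molecule("DT1", kp, seed=seed)
    events = tr.events
    times = [t for t, _, _ in events]
    assert times == sorted(times)
    if tr.active:
        assert events[0][1] == "resume" and events[0][0] == 0.0
        t = np.linspace(0, 600, 300)
        border = np.asarray(tr.rloop_upstream_border(t))
        real = border[~np.isnan(border)]
        if real.size:
            assert np.all(np.diff(real) <= 1e-9) and real.min() >= 1.0
        n_ab = np.asarray(tr.n_antibody(t))
        assert np.all(np.diff(n_ab) >= 0)
    else:
        assert tr.branch is None


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        rl.KineticParams(p_branch=(0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        rl.KineticParams(t_obs=-1.0)
    with pytest.raises(ValueError):
        rl.KineticParams(f_hindrance=0.0)
    with pytest.raises(ValueError):
        rl.simulate_molecule("DT1", rl.preset_kinetics("DT1"), 1,
                             force_branch="sideways")
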