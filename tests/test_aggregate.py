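import numpy as np
import pandas as pd
import pytest

import rlooptrace as rl
from rlooptrace.aggregate import merge_summaries
from rlooptrace.templates import overhang_series


def _calls(classes, **extra):
    n = len(classes)
    base = dict(
        molecule_id=range(n), active=[c != "inactive" for c in classes],
        event_class=classes, t_resume=0.0, t_ab_onset=np.nan,
        t_cy3_loss=np.nan, t_highfret_entry=np.nan, t_pife_onset=np.nan,
        n_ab_steps=0, qc_flags="",
    )
    base.update(extra)
    return pd.DataFrame(base)


def test_wilson_interval_closed_form():
    lo, hi = rl.wilson_interval(73, 100)
    assert lo == pytest.approx(0.6357, abs=5e-4)
    assert hi == pytest.approx(0.8073, abs=5e-4)


def test_summary_trivial_and_merge():
    s = rl.summarize_cohort(_calls(["rloop"] * 10))
    assert s.fractions["rloop"] == 1.0
    assert s.intervals["rloop"][1] == pytest.approx(1.0)
    a = rl.summarize_cohort(_calls(["rloop"] * 73 + ["runoff"] * 27))
    b = rl.summarize_cohort(_calls(["rloop"] * 10 + ["retention"] * 10))
    m = merge_summaries(a, b)
    assert m.n_active == 120 and m.n_by_class["rloop"] == 83
    with pytest.raises(ValueError):
        rl.summarize_cohort(_calls([]))


def test_extension_speed_closed_form_on_landmark_means():
    # downstream drop leads the antibody by 10 s; mid and +1 sites lag it
    res = rl.estimate_extension_speed([(101, -10.0), (33, 9.1), (1, 25.0)])
    assert res["speed"] == pytest.approx(2.880, abs=0.01)
    lo, hi = res["pairwise_range"]
    assert lo == pytest.approx(2.0, abs=0.05)
    assert hi == pytest.approx(3.6, abs=0.05)
    assert rl.estimate_extension_speed([(21, 0.0), (1, 10.0)])["speed"] == \
        pytest.approx(2.0)
    with pytest.raises(ValueError):
        rl.estimate_extension_speed([(10, 1.0)])
    with pytest.raises(ValueError):
        rl.estimate_extension_speed([(10, 1.0), (20, 1.0)])


@pytest.mark.parametrize("v_ext", [1.0, 3.0, 10.0])
def test_extension_speed_recovery_from_ground_truth(v_ext):
    kp = rl.preset_kinetics("DT3", p_branch=(1, 0, 0), p_inactive=0.0,
                            v_ext=v_ext)
    trajs = rl.simulate_cohort("DT3", kp, 400, seed=5)
    rows = []
    for tr in trajs:
        if not len(tr.ab_times):
            continue
        t_ab = tr.ab_times[0]
        for pos in (101, 33, 1):
            t_pos = tr.t_rloop_init + (101 - pos) / v_ext
            rows.append(dict(molecule=tr.molecule_id, position=pos,
                             time=t_pos - t_ab))
    res = rl.estimate_extension_speed(per_molecule=pd.DataFrame(rows),
                                      n_boot=200, seed=1)
    assert res["speed"] == pytest.approx(v_ext, rel=0.10)
    lo, hi = res["interval"]
    assert lo <= v_ext <= hi


def test_overhang_dependence_recovers_configured_trend(optics, cfg):
    summaries = {}
    for tpl, p_rl in overhang_series("overhang3"):
        kp = rl.preset_kinetics("DT1", p_branch=(p_rl, 1 - p_rl - 0.02, 0.02))
        trajs = rl.simulate_cohort(tpl, kp, 200, seed=tpl.overhang_len)
        traces = rl.render_cohort(trajs, optics, seed=tpl.overhang_len + 1)
        calls = rl.classify_cohort(traces, cfg)
        summaries[("3p", tpl.overhang_len)] = rl.summarize_cohort(
            calls, tpl.name)
    table = rl.overhang_dependence_table(summaries)
    trend = table.attrs["trends"]["3p"]
    assert trend["spearman_rho"] > 0
    assert trend["p_value"] < 0.05
    # shuffled input gives the same sorted table
    shuffled = dict(reversed(list(summaries.items())))
    assert rl.overhang_dependence_table(shuffled).equals(table)
    # a single row still forms a table, with no trend statistic
    single = rl.overhang_dependence_table(
        {("3p", 20): summaries[("3p", 20)]})
    assert len(single) == 1 and single.attrs["trends"] == {}
    with pytest.raises(ValueError, match="duplicate"):
        rl.overhang_dependence_table(
            [(("3p", 20), summaries[("3p", 20)])] * 2)


def test_highfret_curve_flat_without_rloops(optics, cfg):
    kp = rl.preset_kinetics("DT3", p_branch=(0, 0.98, 0.02))
    trajs = rl.simulate_cohort("DT3", kp, 60, seed=3)
    traces = rl.render_cohort(trajs, optics, seed=4)
    calls = rl.classify_cohort(traces, cfg)
    curve = rl.highfret_population_curve(
        traces, np.linspace(10, 590, 30), cfg, calls=calls)
    assert np.nanmax(curve["high_fret_fraction"]) < 0.05


def test_highfret_curve_steps_for_synchronized_cohort(noiseless, cfg_noiseless):
    kp = rl.preset_kinetics("DT3", p_branch=(1, 0, 0), p_inactive=0.0,
                            k_rloop_init=1e9)
    trajs = rl.simulate_cohort("DT3", kp, 30, seed=5, force_branch="rloop")
    t_star = trajs[0].t_border_p1
    traces = rl.render_cohort(trajs, noiseless, seed=6)
    grid = np.array([t_star - 10.0, t_star + 10.0])
    curve = rl.highfret_population_curve(traces, grid, cfg_noiseless)
    assert curve["high_fret_fraction"].iloc[0] == pytest.approx(0.0)
    assert curve["high_fret_fraction"].iloc[1] == pytest.approx(1.0)


def test_highfret_population_rises_but_stays_minor_on_blunt_end(optics, cfg):
    kp = rl.preset_kinetics("DT3")
    trajs = rl.simulate_cohort("DT3", kp, 400, seed=7)
    traces = rl.render_cohort(trajs, optics, seed=8)
    calls = rl.classify_cohort(traces, cfg)
    curve = rl.highfret_population_curve(
        traces, np.linspace(5, 595, 40), cfg, calls=calls)
    assert curve.attrs["mann_kendall_tau"] > 0
    assert curve["high_fret_fraction"].iloc[-1] < 0.5


def test_blocking_reinit_vs_control_and_rnaseh_decay():
    losses = rl.run_blocking_experiment(400, seed=9, detected=False)
    grid = np.linspace(180.0, 780.0, 301)
    curve = rl.blocked_fraction_curve(losses, grid, t_add=180.0)
    # pressure on a fully extended R-loop barely moves the retaining fraction
    assert abs(curve["reinit"].iloc[-1] - curve["control"].iloc[-1]) < 0.05
    # the RNase H arm decays with the configured half-life (ln2 / k_rnaseh)
    hl = rl.survival_half_life(curve, "rnaseh", t_add=180.0)
    assert hl == pytest.approx(np.log(2) / 0.05, rel=0.15)
    with pytest.raises(ValueError):
        rl.blocked_fraction_curve(losses.drop(columns="arm"), grid)


def test_no_rloop_cohort_decays_at_reinit_rate():
    kp = rl.preset_kinetics("DT3", p_branch=(0, 0, 1), p_inactive=0.0,
                            k_reinit=0.02)
    trajs = rl.simulate_cohort("DT3", kp, 500, seed=10,
                               force_branch="retention")
    out = [rl.simulate_reinitiation(t, kp, 0.0) for t in trajs]
    losses = np.array([t.t_rna_loss for t in out if t.t_rna_loss is not None])
    assert len(losses) > 480
    assert losses.mean() == pytest.approx(1 / 0.02, rel=0.15)


def test_summaries_invariant_under_reordering(dt1_calls):
    _, calls = dt1_calls
    s1 = rl.summarize_cohort(calls, "DT1")
    s2 = rl.summarize_cohort(calls.sample(frac=1.0, random_state=0), "DT1")
    assert s1.fractions == s2.fractions
    assert s1.mean_t_ab_onset == pytest.approx(s2.mean_t_ab_onset)
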