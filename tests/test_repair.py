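"""NHEJ repair state machine: kinetics, diffusion, curves, fitting."""

import numpy as np
import pytest
from scipy import stats

import radfate as rf
from radfate.damage import Pathway
from radfate.repair import (
    RepairParams,
    fit_biexponential,
    random_walk_step,
    repair_curve,
    simulate_repair,
    step_transition_probability,
)

FAST_CHAIN_MEAN_S = 0.1 + 3.0 + 72.0 + 180.0 + 240.0  # serial mean waiting times


def test_step_probability_identities():
    k = 2.0
    assert step_transition_probability(k, np.log(2) / k) == pytest.approx(0.5)
    # first-order limit: p/(k dt) -> 1
    assert step_transition_probability(k, 1e-9) / (k * 1e-9) == pytest.approx(1.0, rel=1e-6)
    with pytest.raises(ValueError):
        step_transition_probability(-1.0, 0.1)
    with pytest.raises(ValueError):
        step_transition_probability(1.0, 0.0)


def test_stepwise_waiting_times_are_exponential():
    """Geometric step waiting (jittered within the step) matches Exp(k)."""
    k, dt, n = 0.5, 0.02, 100_000
    rng = np.random.default_rng(15)
    p = step_transition_probability(k, dt)
    steps = rng.geometric(p, size=n)
    waits = (steps - rng.random(n)) * dt  # uniform jitter inside the firing step
    d, pval = stats.kstest(waits, "expon", args=(0, 1 / k))
    assert pval > 0.01


def test_random_walk_zero_diffusion_is_identity():
    rng = np.random.default_rng(0)
    c = np.array([1.0, 2.0, 3.0])
    np.testing.assert_array_equal(random_walk_step(c, 0.0, 1.0, rng), c)


def test_random_walk_msd_matches_brownian():
    """Ensemble MSD after time t equals 6 D t (unbounded domain)."""
    rng = np.random.default_rng(16)
    D, dt, n_steps, n_walk = 2.0, 0.5, 40, 10_000
    pos = np.zeros((n_walk, 3))
    for _ in range(n_steps):
        pos += rng.normal(0.0, np.sqrt(2 * D * dt), size=(n_walk, 3))
    sq = np.sum(pos**2, axis=1)
    expected = 6 * D * dt * n_steps
    tol = 3.0 * np.std(sq) / np.sqrt(n_walk)
    assert abs(np.mean(sq) - expected) < tol


def test_random_walk_reflection_keeps_inside():
    rng = np.random.default_rng(17)
    c = np.zeros(3)
    for _ in range(2000):
        c = random_walk_step(c, 50.0, 1.0, rng, nucleus_radius=30.0)
        assert np.linalg.norm(c) <= 30.0 + 1e-9


def test_fast_chain_mean_matches_serial_oracle(single_dsb_factory):
    """Co-located fast pair: mean completion ~ sum of step mean times."""
    times = []
    for seed in range(300):
        traj = simulate_repair(
            single_dsb_factory(Pathway.FAST), RepairParams(t_max=4 * 3600), seed=seed
        )
        times.append(traj.events[0].completion_time)
    tol = 3.0 * np.std(times) / np.sqrt(len(times))
    assert abs(np.mean(times) - FAST_CHAIN_MEAN_S) < tol


def test_all_fast_damage_completes():
    d = rf.generate_damage(2.0, seed=18)
    d = rf.assign_pathways(d, seed=19, forced_f_slow=0.0)
    traj = simulate_repair(d, RepairParams(t_max=6 * 3600), seed=20)
    assert traj.unrepaired_count[-1] == 0
    assert len(traj.events) == traj.n_initial


def test_artemis_deficiency_stalls_slow_pathway(single_dsb_factory):
    traj = simulate_repair(
        single_dsb_factory(Pathway.SLOW),
        RepairParams(t_max=24 * 3600, artemis_active=False),
        seed=21,
    )
    assert traj.events == []
    assert traj.unrepaired_count[-1] == 1


def test_unassigned_pathway_rejected(damage_2gy):
    with pytest.raises(ValueError):
        simulate_repair(damage_2gy, RepairParams(t_max=60.0), seed=0)


def test_dt_guard():
    with pytest.raises(ValueError):
        RepairParams(dt=0.06)  # k1*dt = 0.6 > 0.5
    with pytest.warns(UserWarning):
        RepairParams(dt=0.02)  # k1*dt = 0.2 > 0.1


def test_trajectory_invariants_and_conservation():
    d = rf.generate_damage(2.0, seed=22)
    d = rf.assign_pathways(d, seed=23, forced_f_slow=0.5)
    traj = simulate_repair(d, RepairParams(t_max=12 * 3600), seed=24)
    assert np.all(np.diff(traj.unrepaired_count) <= 0)
    assert np.all(traj.unrepaired_count >= 0)
    assert len(traj.events) + traj.unrepaired_count[-1] == traj.n_initial


def test_fixed_seed_reproducible():
    d = rf.generate_damage(1.0, seed=25)
    d = rf.assign_pathways(d, seed=26, forced_f_slow=0.3)
    t1 = simulate_repair(d, RepairParams(t_max=12 * 3600), seed=27)
    t2 = simulate_repair(d, RepairParams(t_max=12 * 3600), seed=27)
    assert [(e.dsb_id, e.completion_time, e.correct_partner) for e in t1.events] == [
        (e.dsb_id, e.completion_time, e.correct_partner) for e in t2.events
    ]


def test_slow_curve_dominates_fast_curve():
    """All-slow unrepaired fraction lies above all-fast at every t > 0."""
    grid = np.linspace(600, 20 * 3600, 30)
    curves = {}
    for fs in (0.0, 1.0):
        ys = []
        for seed in range(5):
            d = rf.generate_damage(2.0, seed=30 + seed)
            d = rf.assign_pathways(d, seed=40 + seed, forced_f_slow=fs)
            traj = simulate_repair(d, RepairParams(t_max=20 * 3600), seed=50 + seed)
            ys.append(repair_curve(traj, grid=grid)[1])
        curves[fs] = np.mean(ys, axis=0)
    assert np.all(curves[1.0] >= curves[0.0])


def test_same_kinetics_for_hc_and_complexity_slow():
    """Slow-by-chromatin and slow-by-complexity DSBs repair alike."""
    means = []
    for hc, cf in [(1.0, 0.0), (0.0, 1.0)]:
        times = []
        for seed in range(40):
            d = rf.generate_damage(1.0, complex_fraction=cf, hc_fraction=hc, seed=60 + seed)
            d = rf.assign_pathways(d, seed=70 + seed)
            traj = simulate_repair(d, RepairParams(t_max=48 * 3600), seed=80 + seed)
            times.extend(e.completion_time for e in traj.events)
        means.append((np.mean(times), np.std(times) / np.sqrt(len(times))))
    (m1, s1), (m2, s2) = means
    assert abs(m1 - m2) < 3.0 * np.hypot(s1, s2)


def test_step_refinement_converges():
    """Halving the step-accuracy cap changes the mean half-time < 2%."""
    def half_time(eps):
        ts = []
        for seed in range(30):
            d = rf.generate_damage(1.0, seed=90 + seed)
            d = rf.assign_pathways(d, seed=100 + seed, forced_f_slow=0.0)
            p = RepairParams(t_max=4 * 3600, step_accuracy=eps)
            traj = simulate_repair(d, p, seed=110 + seed)
            t, y = repair_curve(traj)
            ts.append(t[np.searchsorted(-y, -0.5)])
        return np.mean(ts)

    h1, h2 = half_time(0.02), half_time(0.01)
    assert abs(h1 - h2) / h1 < 0.02


def test_misjoining_increases_with_dose():
    def misjoins(dose):
        total = 0
        for seed in range(5):
            d = rf.generate_damage(dose, nucleus_radius=800.0, seed=120 + seed)
            d = rf.assign_pathways(d, seed=130 + seed, forced_f_slow=0.0)
            traj = simulate_repair(d, RepairParams(t_max=4 * 3600), seed=140 + seed)
            total += sum(1 for e in traj.events if not e.correct_partner)
        return total

    assert misjoins(8.0) > misjoins(0.5)


# --- biexponential fitting --------------------------------------------------

def test_biexponential_selfconsistency():
    t = np.linspace(0, 20 * 3600, 200)
    y = 0.7 * np.exp(-t / 600.0) + 0.3 * np.exp(-t / 18000.0)
    ff, tf, fs, ts = fit_biexponential((t, y))
    assert ff == pytest.approx(0.7, abs=1e-6)
    assert tf == pytest.approx(600.0, rel=1e-5)
    assert fs == pytest.approx(0.3, abs=1e-6)
    assert ts == pytest.approx(18000.0, rel=1e-5)
    assert tf < ts


def test_biexponential_single_exponential_limit():
    t = np.linspace(0, 10 * 3600, 100)
    y = np.exp(-t / 3600.0)
    with pytest.warns(UserWarning, match="degenerate"):
        ff, tf, fs, ts = fit_biexponential((t, y))
    assert min(ff, fs) < 0.05 or ts / tf < 3.0


def test_biexponential_requires_points():
    with pytest.raises(ValueError):
        fit_biexponential((np.array([0.0, 1.0]), np.array([1.0, 0.5])))
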