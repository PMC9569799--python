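"""p53 network: Hill input, topology, ODE and Gillespie engines."""

import numpy as np
import pytest
from scipy.signal import find_peaks

from radfate.p53net import (
    ConfigurationError,
    HillParams,
    Reaction,
    ReactionNetwork,
    atm_activation_rate,
    build_network,
    load_params,
    simulate_deterministic,
    simulate_stochastic,
)


def test_atm_rate_zero_damage():
    assert atm_activation_rate(0.0, 100.0, HillParams()) == 0.0


def test_atm_rate_half_saturation():
    p = HillParams(k=3e-3, m_dsb=17.0, atm_total=500.0)
    saturating = p.k * 123.0
    assert atm_activation_rate(p.m_dsb, 123.0, p) == pytest.approx(saturating / 2)


def test_atm_rate_near_saturation():
    p = HillParams(m_dsb=4.0)
    ratio = atm_activation_rate(40.0, 1.0, p) / (p.k * 1.0)
    assert ratio == pytest.approx(100.0 / 101.0)


def test_atm_rate_domain():
    with pytest.raises(ValueError):
        atm_activation_rate(-1.0, 10.0, HillParams())


def test_network_topology_audit(network):
    """Every documented regulatory edge maps to at least one reaction."""
    edges = set(network.edge_list())
    required = [
        ("DSB", "activation", "ATM_p"),
        ("ATM_p", "catalysis", "p53_arrester"),
        ("ATM_p", "catalysis", "p53_killer"),
        ("Wip1", "activation", "ATM_i"),         # Wip1 shuts ATM off
        ("Wip1", "catalysis", "p53"),            # arrester dephosphorylation
        ("p53_arrester", "activation", "mdm2_mrna"),
        ("p53_arrester", "activation", "wip1_mrna"),
        ("p53_arrester", "activation", "p21_mrna"),
        ("Mdm2", "degradation", "p53"),
        ("p21", "repression", "cyclin_E"),
        ("p53_killer", "activation", "bax_mrna"),
        ("p53_killer", "repression", "Akt_p"),
        ("Akt_p", "degradation", "Bax"),
        ("p21", "activation", "GADD45"),
        ("GADD45", "activation", "p38"),
        ("p38", "activation", "TGFb"),
    ]
    missing = [e for e in required if e not in edges]
    assert not missing, f"missing regulatory edges: {missing}"


def test_missing_constant_is_named(tmp_path):
    params = load_params()
    del params["d_wip1"]
    path = tmp_path / "broken.tsv"
    with open(path, "w") as fh:
        fh.write("name\tvalue\tunit\tsource\n")
        for k, v in params.items():
            fh.write(f"{k}\t{v}\tx\tt\n")
    with pytest.raises(ConfigurationError, match="d_wip1"):
        build_network(path)


def test_dsb_slot_never_consumed(network):
    assert np.all(network._stoich[:, 0] == 0)


def test_zero_synthesis_decays_everything(tmp_path):
    params = load_params()
    for key in list(params):
        if key.startswith("s_") or "_tln" in key:
            params[key] = 0.0
    path = tmp_path / "nosynth.tsv"
    with open(path, "w") as fh:
        fh.write("name\tvalue\tunit\tsource\n")
        for k, v in params.items():
            if k == "m_dsb":
                continue
            fh.write(f"{k}\t{v}\tx\tt\n")
    net = build_network(path)
    x0 = np.zeros(len(net.species))
    x0[1:] = 50.0  # every dynamic species populated ...
    x0[net.index("ATM_p")] = 0.0  # ... but no active kinase: pure decay
    traj = simulate_deterministic(net, 0.0, t_max=600.0, x0=x0, n_grid=200)
    assert np.all(traj.values[-1, 3:] < 0.5)  # all signalling pools drained
    for name in ("Mdm2", "Wip1", "p21", "cyclin_E", "Bax", "TGFb", "p53_killer"):
        y = traj.get(name)
        assert np.all(np.diff(y) <= 1e-6)


def test_basal_state_is_fixed_point(network):
    traj = simulate_deterministic(network, 0.0, t_max=72.0)
    x0, x1 = traj.values[0, 1:], traj.values[-1, 1:]
    assert np.all(np.abs(x1 - x0) <= 0.01 * np.maximum(x0, 1.0))


def test_atm_conservation_both_engines(network):
    total = network.hill.atm_total
    ode = simulate_deterministic(network, 80.0, t_max=24.0)
    np.testing.assert_allclose(ode.get("ATM_i") + ode.get("ATM_p"), total, rtol=1e-4)
    ssa = simulate_stochastic(network, 80.0, t_max=24.0, seed=3)
    np.testing.assert_allclose(ssa.get("ATM_i") + ssa.get("ATM_p"), total, atol=0.5)


def test_ode_nonnegative_and_oscillating(network):
    traj = simulate_deterministic(network, 80.0, t_max=48.0)
    assert np.all(traj.values >= 0)
    y = traj.get("p53_arrester")
    pk, _ = find_peaks(y, prominence=15)
    assert len(pk) >= 4
    period = float(np.mean(np.diff(traj.time_h[pk])))
    assert 5.0 < period < 11.0


def test_atm_amplitude_saturates_with_dose(network):
    amps = []
    for dsb in (80.0, 320.0):  # 2 Gy vs 8 Gy at 40 DSB/Gy
        traj = simulate_deterministic(network, dsb, t_max=12.0)
        amps.append(float(traj.get("ATM_p").max()))
    assert abs(amps[1] - amps[0]) / amps[0] < 0.10


def _pure_death_network(c):
    species = ["DSB", "A"]
    rx = [Reaction("death", "c", (1,), ())]
    return ReactionNetwork(
        species=species, reactions=rx, params={"c": c},
        hill=HillParams(), basal=np.array([0.0, 0.0]),
    )


def test_ssa_pure_death_mean_lifetime():
    """Analytic pure-death process: each copy lives Exp(c) on average."""
    c, n0, n_runs = 0.05, 50, 200
    net = _pure_death_network(c)
    lifetimes = []
    grid = 2001
    for seed in range(n_runs):
        traj = simulate_stochastic(
            net, 0.0, t_max=200.0 / 3600.0, seed=seed,
            x0=np.array([0.0, float(n0)]), n_grid=grid,
        )
        a = traj.get("A")
        t_s = traj.time_h * 3600.0
        deaths = -np.diff(a)
        mids = 0.5 * (t_s[1:] + t_s[:-1])
        lifetimes.extend(np.repeat(mids, deaths.astype(int)))
    mean = np.mean(lifetimes)
    tol = 3.0 * (1 / c) / np.sqrt(len(lifetimes))
    assert abs(mean - 1 / c) < tol + 0.1 / c * 0.0 + 0.05  # grid discretization slack


def test_ssa_seed_determinism(network):
    a = simulate_stochastic(network, 80.0, t_max=6.0, seed=7)
    b = simulate_stochastic(network, 80.0, t_max=6.0, seed=7)
    np.testing.assert_array_equal(a.values, b.values)
    c = simulate_stochastic(network, 80.0, t_max=6.0, seed=8)
    assert not np.array_equal(a.values, c.values)


def test_ssa_integer_nonnegative(network):
    traj = simulate_stochastic(network, 80.0, t_max=6.0, seed=9)
    assert np.all(traj.values >= 0)
    np.testing.assert_array_equal(traj.values, np.round(traj.values))


def test_scaled_network_preserves_mean_field(network):
    """10x copy scaling leaves the ODE levels 10x and dynamics intact."""
    net10 = network.scaled(10.0)
    a = simulate_deterministic(network, 80.0, t_max=6.0)
    b = simulate_deterministic(net10, 80.0, t_max=6.0)
    np.testing.assert_allclose(
        b.values[:, 1:], 10.0 * a.values[:, 1:], rtol=5e-3, atol=0.5
    )
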