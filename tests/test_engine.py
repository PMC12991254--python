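"""Stochastic engine: substep statistics, bookkeeping, and invariants."""

import numpy as np
import pytest

import phagesim as ps
from phagesim.engine import HEALTHY, INFECTED_MU, INFECTED_WT, Simulation
from phagesim.life_history import BacteriumParams


def serial_cfg(**kw):
    wt = kw.pop("wt", ps.default_strain("wildtype", "linear_with_eclipse"))
    mu = kw.pop("mu", ps.default_strain("mutant", "linear_with_eclipse"))
    return ps.serial_passage_config(wt, mu, **kw)


# ---------------------------------------------------------------------------
# initialization


def test_serial_passage_initialization():
    sim = Simulation(serial_cfg(), 1)
    h, iw, im = sim.state_counts()
    assert (h, iw, im) == (10_000, 0, 0)
    assert sim.V.tolist() == [[100, 100]]
    assert sim.time == 0.0
    assert np.all(sim.g_elapsed[: sim.n] <= sim.g_cycle[: sim.n])
    assert np.all(sim.g_elapsed[: sim.n] >= 0.0)


def test_plaque_initialization():
    sim = Simulation(ps.plaque_config(), 1)
    counts = sim.deme_cell_counts()
    assert counts.shape == (60,)
    assert np.all(counts == 100)
    assert sim.V[0].tolist() == [100, 100]
    assert sim.V[1:].sum() == 0


def test_phage_free_initialization():
    sim = Simulation(serial_cfg(v0=(0, 0)), 1)
    assert sim.V.sum() == 0 and sim.n == 10_000


# ---------------------------------------------------------------------------
# adsorption


def test_adsorption_event_rate_matches_poisson_mean():
    """Mean successful adsorptions per step ~ αBVΔt/Vol = 3.0 with default
    parameters and negligible receptor occupancy."""
    cfg = serial_cfg()
    sim = Simulation(cfg, 2)
    total, n_iter = 0, 3000
    for _ in range(n_iter):
        sim.V[0] = (100, 100)
        sim.ads[: sim.n] = 0
        sim.ads_tot[: sim.n] = 0
        sim.tallies = {}
        sim.step_adsorption()
        total += int(sim.tallies["adsorbed"][0])
    mean = total / n_iter
    se = np.sqrt(3.0 / n_iter)
    assert abs(mean - 3.0) < 4 * se


def test_adsorption_zero_virions_is_noop():
    sim = Simulation(serial_cfg(v0=(0, 0)), 3)
    sim.tallies = {}
    sim.step_adsorption()
    assert sim.tallies["adsorbed"].sum() == 0


def test_full_occupancy_blocks_adsorption_without_consuming_virion():
    """With Amax=1 a fully occupied cell rejects every event and the free
    pool is untouched (super-adsorption disabled)."""
    cfg = serial_cfg(
        b0=1, v0=(500, 0), bacterium=BacteriumParams(20.0, 2.0, max_adsorbed=1)
    )
    sim = Simulation(cfg, 4)
    sim.ads[0, 0] = 1
    sim.ads_tot[0] = 1
    sim.state[0] = INFECTED_WT
    for _ in range(200):
        sim.tallies = {}
        sim.step_adsorption()
        assert sim.tallies["adsorbed"].sum() == 0
    assert sim.V[0, 0] == 500


def test_adsorption_success_consumes_virion_and_occupies_receptor():
    cfg = serial_cfg(b0=1, v0=(10_000, 0), volume=1e-8)
    sim = Simulation(cfg, 5)
    sim.tallies = {}
    sim.step_adsorption()
    used = int(sim.tallies["adsorbed"][0])
    assert used > 0
    assert sim.V[0, 0] == 10_000 - used
    assert sim.ads[0, 0] == used
    assert sim.ads_tot[0] <= sim.bacterium.max_adsorbed


# ---------------------------------------------------------------------------
# infection


def test_infection_deterministic_when_one_strain_adsorbed():
    sim = Simulation(serial_cfg(), 6)
    sim.ads[0] = (2, 0)
    sim.ads_tot[0] = 2
    sim.tallies = {}
    sim.step_infection()
    assert sim.state[0] == INFECTED_WT
    assert sim.l_time[0] > 0


def test_infection_binomial_on_mixed_adsorption(rng):
    sim = Simulation(serial_cfg(), 7)
    k = 10_000
    sim.ads[:k] = (1, 1)
    sim.ads_tot[:k] = 2
    sim.tallies = {}
    sim.step_infection()
    n_mu = int((sim.state[:k] == INFECTED_MU).sum())
    se = np.sqrt(0.25 * k)
    assert abs(n_mu - k / 2) < 4 * se


def test_first_infection_fixes_cell_fate():
    sim = Simulation(serial_cfg(), 8)
    sim.ads[0] = (1, 0)
    sim.ads_tot[0] = 1
    sim.tallies = {}
    sim.step_infection()
    tau0 = sim.l_time[0]
    # further (super-)adsorption of the other strain changes nothing
    sim.ads[0] = (1, 5)
    sim.ads_tot[0] = 6
    sim.tallies = {}
    sim.step_infection()
    assert sim.state[0] == INFECTED_WT
    assert sim.l_time[0] == tau0


# ---------------------------------------------------------------------------
# growth and lysis


def test_growth_deferred_at_carrying_capacity():
    cfg = serial_cfg(b0=100, carrying_capacity=100, v0=(0, 0))
    sim = Simulation(cfg, 9)
    sim.g_elapsed[: sim.n] = sim.g_cycle[: sim.n]  # everyone ready to divide
    sim.tallies = {}
    sim.step_growth()
    assert sim.tallies["divisions"] == 0
    assert sim.n == 100


def test_infected_cells_do_not_divide():
    sim = Simulation(serial_cfg(b0=10, v0=(0, 0)), 10)
    sim.state[: sim.n] = INFECTED_WT
    sim.l_time[: sim.n] = 1e9
    sim.g_elapsed[: sim.n] = sim.g_cycle[: sim.n] + 1.0
    sim.tallies = {}
    sim.step_growth()
    assert sim.tallies["divisions"] == 0


def test_lysis_releases_calibrated_burst():
    sim = Simulation(serial_cfg(), 11)
    sim.state[0] = INFECTED_WT
    sim.l_time[0] = 17.0
    sim.l_elapsed[0] = 17.0
    n_before = sim.n
    sim.tallies = {}
    sim.step_lysis()
    assert sim.tallies["released"][0] == 150  # eclipse model: 20*(17-9.5)
    assert sim.n == n_before - 1
    assert sim.V[0, 0] == 100 + 150


def test_lysis_below_eclipse_releases_nothing():
    sim = Simulation(serial_cfg(), 12)
    sim.state[0] = INFECTED_MU
    sim.l_time[0] = 8.0
    sim.l_elapsed[0] = 8.0
    n_before = sim.n
    sim.tallies = {}
    sim.step_lysis()
    assert sim.tallies["released"][1] == 0
    assert sim.n == n_before - 1


def test_lysis_noop_without_infected_cells():
    sim = Simulation(serial_cfg(), 13)
    v = sim.V.copy()
    sim.tallies = {}
    sim.step_lysis()
    assert np.array_equal(sim.V, v) and sim.n == 10_000


# ---------------------------------------------------------------------------
# decay and diffusion


def test_decay_statistics_and_conservative_mode():
    sim = Simulation(serial_cfg(), 14)
    lost, n_iter = 0, 10_000
    for _ in range(n_iter):
        sim.V[0] = (1000, 0)
        sim.tallies = {}
        sim.step_decay()
        lost += int(sim.tallies["decayed"][0])
    mean = lost / n_iter  # δVΔt = 0.01*1000*0.01 = 0.1
    assert abs(mean - 0.1) < 4 * np.sqrt(0.1 / n_iter)

    cons = Simulation(serial_cfg(conservative=True), 15)
    cons.V[0] = (1000, 1000)
    cons.tallies = {}
    cons.step_decay()
    assert cons.tallies["decayed"].sum() == 0


def test_diffusion_mean_and_conservation():
    cfg = ps.plaque_config(v0=(1000, 0))
    sim = Simulation(cfg, 16)
    moved = 0
    n_iter = 2000
    for _ in range(n_iter):
        sim.V[:] = 0
        sim.V[30, 0] = 1000  # interior deme: two directions
        sim.tallies = {}
        sim.step_diffusion()
        assert sim.V.sum() == 1000  # conservation every step
        moved += int(sim.tallies["migrated"][0])
    # per-direction mean DVΔt/(2Δx²) = 240*1000*0.01/200 = 12 -> 24 total
    assert abs(moved / n_iter - 24.0) < 4 * np.sqrt(24.0 / n_iter)


def test_diffusion_noop_cases():
    sim = Simulation(serial_cfg(), 17)
    sim.tallies = {}
    sim.step_diffusion()  # single deme
    assert sim.tallies["migrated"].sum() == 0
    plq = Simulation(ps.plaque_config(v0=(0, 0)), 18)
    plq.tallies = {}
    plq.step_diffusion()
    assert plq.V.sum() == 0


# ---------------------------------------------------------------------------
# treadmill and transfer


def test_treadmill_shifts_only_past_threshold():
    sim = Simulation(ps.plaque_config(), 19)
    sim.V[:] = 0
    sim.V[10, 0] = 500
    sim.apply_treadmill()
    assert sim.cumulative_shift == 0

    sim.V[:] = 0
    sim.V[31, 0] = 500
    counts_before = sim.deme_cell_counts()
    sim.apply_treadmill()
    assert sim.cumulative_shift == 1
    counts = sim.deme_cell_counts()
    assert counts.shape == (60,)
    assert counts[-1] == 100  # fresh deme at the right edge
    assert sim.V[30, 0] == 500  # peak moved one deme left
    assert sim.front_position() == (30 + 1) * 10.0


def test_transfer_trigger_and_thinning():
    cfg = serial_cfg()
    sim = Simulation(cfg, 20)
    # force the culture below 1% of B0
    sim._delete_rows(np.arange(99, sim.n))
    assert sim.n == 99
    sim.V[0] = (1_000_000, 0)
    sim.state[0] = INFECTED_WT
    sim.l_time[0] = 17.0
    sim.l_elapsed[0] = 3.0
    sim.tallies = {}
    assert sim._transfer_due()
    sim.apply_transfer()
    assert sim.n_transfers == 1
    # ~ Binomial(1e6, 1e-3): mean 1000, sd ~31.6
    assert abs(sim.V[0, 0] - 1000) < 6 * 31.6
    assert sim.state_counts()[0] >= 10_000  # fresh healthy cells added
    # surviving infected cell (if any) retained its clock mid-countdown
    inf = np.nonzero(sim.state[: sim.n] == INFECTED_WT)[0]
    for i in inf:
        assert sim.l_time[i] == 17.0 and sim.l_elapsed[i] == 3.0


def test_fixed_interval_transfer_fires_on_schedule():
    cfg = serial_cfg(transfer_interval=30.0, t_max=95.0, v0=(0, 0))
    sim = Simulation(cfg, 21)
    sim.run()
    assert sim.n_transfers == 3  # at 30, 60 and 90 minutes


# ---------------------------------------------------------------------------
# whole-step invariants


def test_empty_world_advances_time_only():
    cfg = serial_cfg(b0=0, v0=(0, 0), transfer_enabled=False, t_max=1.0)
    sim = Simulation(cfg, 22)
    sim.run()
    assert sim.time == pytest.approx(1.0)
    assert sim.n == 0 and sim.V.sum() == 0


def test_identical_seeds_give_identical_trajectories():
    cfg = serial_cfg(t_max=30.0)
    t1 = Simulation(cfg, 77)
    t1.run()
    t2 = Simulation(cfg, 77)
    t2.run()
    assert t1.trajectory.equals(t2.trajectory)
    t3 = Simulation(cfg, 78)
    t3.run()
    assert not t1.trajectory.equals(t3.trajectory)


def test_virion_balance_ledger_every_step():
    """Per step: ΔV_total = releases − successful adsorptions − decays
    (diffusion only moves virions within the lattice)."""
    cfg = ps.scale_system(serial_cfg(t_max=120.0), 0.1)
    sim = Simulation(cfg, 23)
    steps = 0

    def check(s):
        nonlocal steps
        steps += 1
        if not s.tallies["transferred"]:
            expected = (
                int(s.tallies["released"].sum())
                - int(s.tallies["adsorbed"].sum())
                - int(s.tallies["decayed"].sum())
            )
            assert s.tallies["virion_delta"] == expected
        assert np.all(s.V >= 0)
        return None

    sim.run(stop=check)
    assert steps == 12_000


def test_single_infection_conservative_creates_exactly_one_burst():
    """One virion, one bacterium, no decay: the total virions ever created
    equal the single sampled burst, and nothing else happens."""
    cfg = serial_cfg(
        b0=1, v0=(1, 0), volume=1e-9, conservative=True,
        transfer_enabled=False, t_max=60.0,
    )
    sim = Simulation(cfg, 24)
    sim.run()
    released = int(sim.cum_released[0])
    assert released > 0  # lysis happened within 60 min
    assert sim.cum_released[1] == 0
    # no hosts remain, so every released virion is still free
    assert int(sim.V.sum()) == released
    assert sim.state_counts()[1:] == (0, 0)


def test_adsorption_curve_matches_mass_action():
    """With lysis effectively disabled, free virions decline at rate
    ≈ αB/Vol per virion (the textbook adsorption curve)."""
    from scipy import stats

    wt = ps.default_strain("wildtype", "normal", 1e5, 1.0, decay_rate=0.0)
    cfg = ps.serial_passage_config(
        wt, wt, v0=(10_000, 0), transfer_enabled=False, t_max=1.5
    )
    sim = Simulation(cfg, 25)
    sim.run()
    tr = sim.trajectory
    t = tr["time"].to_numpy()
    v = tr["v_wt"].to_numpy(float)
    m = v > 0
    slope = stats.linregress(t[m], np.log(v[m])).slope
    assert slope == pytest.approx(-3.0, rel=0.15)


def test_event_log_ndjson_round_trips(tmp_path):
    import json

    cfg = serial_cfg(t_max=0.5, record_events=True, v0=(100, 100))
    sim = Simulation(cfg, 26)
    sim.run()
    assert len(sim.event_log) == 50
    path = tmp_path / "events.ndjson"
    sim.write_event_log_ndjson(path)
    lines = path.read_text().splitlines()
    assert len(lines) == 50
    entry = json.loads(lines[0])
    assert {"time", "adsorbed", "released", "decayed", "virion_delta"} <= entry.keys()
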