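"""Competition protocols and fitness estimators.

Two laboratory protocols are emulated:

* **Serial passage** — a well-mixed culture repeatedly diluted 1000× into
  fresh hosts once 99% of the bacteria have been lysed.  The run ends
  when one free-virion pool outnumbers the other 70:30 (that strain is
  the winner), when one strain goes extinct, or at t_max.
* **Plaque expansion** — a 1-D lattice of demes with virion diffusion and
  a treadmill window; runs for a fixed time, fixation assessed at the end
  with the same 70:30 rule on lattice-total free virions.

Fitness is quantified three ways: fixation probability across replicate
runs, the selection-rate difference ΔF = d/dt ln(V_mu/V_wt) fitted by
ordinary least squares on the sampled trajectory, and (plaque only) the
infection-front velocity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .engine import SimConfig, Simulation

__all__ = [
    "CompetitionOutcome",
    "FitnessEstimate",
    "FrontVelocityEstimate",
    "FixationEstimate",
    "run_serial_passage",
    "run_serial_passage_fixed_interval",
    "run_plaque_expansion",
    "estimate_fixation_probability",
    "estimate_fitness_difference",
    "estimate_front_velocity",
    "dead_time_diagnostic",
]

FIXATION_RATIO = 0.7
FIXATION_MIN_VIRIONS = 100  # gate: don't call winners from a near-empty pool
FIXATION_SUSTAIN_MINUTES = 10.0  # dominance must persist, not flash at a burst


@dataclass
class CompetitionOutcome:
    winner: str  # "wildtype" | "mutant" | "none"
    termination_time: float
    n_transfers: int
    trajectory: pd.DataFrame
    dead_time_log: list[dict]

    @property
    def decided(self) -> bool:
        return self.winner != "none"


@dataclass(frozen=True)
class FitnessEstimate:
    """OLS slope of ln(V_mu/V_wt) vs time: ΔF [1/min]."""

    delta_f: float
    stderr: float
    window: tuple[float, float]
    n_samples: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.delta_f)


@dataclass(frozen=True)
class FrontVelocityEstimate:
    velocity: float  # μm/min
    stderr: float
    window: tuple[float, float]
    expanded: bool = True


@dataclass(frozen=True)
class FixationEstimate:
    probability: float
    ci_low: float
    ci_high: float
    n_mutant: int
    n_wildtype: int
    n_none: int


def _ratio_winner(v, gate: int = FIXATION_MIN_VIRIONS) -> str | None:
    """Apply the 70:30 rule to a per-strain free-virion pool."""
    total = int(v[0]) + int(v[1])
    if total >= gate:
        if v[0] >= FIXATION_RATIO * total:
            return "wildtype"
        if v[1] >= FIXATION_RATIO * total:
            return "mutant"
    return None


class WinnerMonitor:
    """Per-step termination check for serial passage.

    Extinction (no free virions and no infected cells of a strain) ends
    the run at any step.  The 70:30 free-virion rule is applied to
    *sustained* dominance: with tightly synchronized lysis the
    instantaneous pool share swings to ~100:0 at every burst (the very
    first burst of a run would otherwise always decide it), so one pool
    must hold at least 70% of a non-negligible total continuously for
    ``FIXATION_SUSTAIN_MINUTES`` before its strain is declared fixed.
    Dilution transfers preserve the pool share in expectation, so a
    streak may span a transfer.
    """

    def __init__(self):
        self._streak_strain: int | None = None
        self._streak_since: float = 0.0

    def __call__(self, sim: Simulation) -> str | None:
        v = sim.total_virions()
        inf = sim.infected_counts()
        alive = (v > 0) | (inf > 0)
        if not alive[1] and alive[0]:
            return "wildtype"
        if not alive[0] and alive[1]:
            return "mutant"
        if not alive[0] and not alive[1]:
            return "none"
        total = int(v.sum())
        leader: int | None = None
        if total >= FIXATION_MIN_VIRIONS:
            if v[0] >= FIXATION_RATIO * total:
                leader = 0
            elif v[1] >= FIXATION_RATIO * total:
                leader = 1
        if leader is None or leader != self._streak_strain:
            self._streak_strain = leader
            self._streak_since = sim.time
            return None
        if sim.time - self._streak_since >= FIXATION_SUSTAIN_MINUTES:
            return "wildtype" if leader == 0 else "mutant"
        return None


def run_serial_passage(
    config: SimConfig, seed: int = 0, stop_at_fixation: bool = True
) -> CompetitionOutcome:
    """Run one serial-passage competition to fixation, extinction or t_max.

    With ``stop_at_fixation=False`` the run continues to t_max while the
    first fixation/extinction verdict is still recorded as the winner;
    this yields multi-passage trajectories for selection-rate (ΔF)
    estimation even for quickly decided competitions.
    """
    if config.n_demes != 1:
        raise ValueError("serial passage requires a single well-mixed deme")
    sim = Simulation(config, seed)
    monitor = WinnerMonitor()
    if stop_at_fixation:
        verdict = sim.run(stop=monitor)
        termination = sim.time
    else:
        first: list[str] = []

        def observe(s):
            if not first:
                v = monitor(s)
                if v:
                    first.append(v)
            return None

        sim.run(stop=observe)
        verdict = first[0] if first else None
        termination = sim.time
    if verdict is None:
        # undecided at t_max: apply the ratio rule to the final pools
        verdict = _ratio_winner(sim.total_virions())
    return CompetitionOutcome(
        winner=verdict or "none",
        termination_time=termination,
        n_transfers=sim.n_transfers,
        trajectory=sim.trajectory,
        dead_time_log=sim.dead_time_log,
    )


def run_serial_passage_fixed_interval(
    config: SimConfig, interval: float, seed: int = 0
) -> CompetitionOutcome:
    """Serial passage with transfers at a fixed interval (minutes) instead
    of being triggered by lysis of 99% of the culture."""
    return run_serial_passage(replace(config, transfer_interval=interval), seed)


def run_plaque_expansion(
    config: SimConfig, seed: int = 0
) -> tuple[CompetitionOutcome, FrontVelocityEstimate]:
    """Run one plaque-expansion competition for the configured duration."""
    if config.n_demes < 2:
        raise ValueError("plaque expansion requires multiple demes")
    sim = Simulation(config, seed)
    sim.run()
    v = sim.total_virions()
    total = int(v.sum())
    winner = "none"
    if total > 0:
        if v[0] >= FIXATION_RATIO * total:
            winner = "wildtype"
        elif v[1] >= FIXATION_RATIO * total:
            winner = "mutant"
    outcome = CompetitionOutcome(
        winner=winner,
        termination_time=sim.time,
        n_transfers=0,
        trajectory=sim.trajectory,
        dead_time_log=[],
    )
    return outcome, estimate_front_velocity(sim.trajectory)


def estimate_fitness_difference(
    trajectory: pd.DataFrame, window: tuple[float, float] | None = None
) -> FitnessEstimate:
    """ΔF = d/dt ln(V_mu/V_wt) by OLS on the sampled trajectory.

    Samples where either free-virion counter is zero are excluded; fewer
    than 3 usable samples yields a NaN (undefined) estimate.
    """
    t = trajectory["time"].to_numpy()
    vw = trajectory["v_wt"].to_numpy(dtype=float)
    vm = trajectory["v_mu"].to_numpy(dtype=float)
    mask = (vw > 0) & (vm > 0)
    if window is not None:
        mask &= (t >= window[0]) & (t <= window[1])
    t, vw, vm = t[mask], vw[mask], vm[mask]
    if len(t) < 3 or t[-1] == t[0]:
        win = (float("nan"), float("nan")) if len(t) == 0 else (t[0], t[-1])
        return FitnessEstimate(float("nan"), float("nan"), win, len(t))
    res = stats.linregress(t, np.log(vm / vw))
    return FitnessEstimate(
        float(res.slope), float(res.stderr), (float(t[0]), float(t[-1])), len(t)
    )


def estimate_fitness_from_transfers(outcome: CompetitionOutcome) -> FitnessEstimate:
    """ΔF from the pre-dilution pools at the passage boundaries.

    When lysis is tightly synchronized the free pools drain to zero
    between bursts and the per-minute estimator has no usable samples;
    the pool ratio at the end of each passage is still well defined, so
    ΔF is fitted as the OLS slope of ln(V_mu/V_wt) against transfer time,
    anchored at the initial inoculum ratio at t = 0.  An extinct pool is
    floored at one virion so that lost strains register as a strongly
    negative (finite) rate rather than as missing data.
    """
    times, lnr = [], []
    traj0 = outcome.trajectory.iloc[0]
    if traj0["v_wt"] > 0 and traj0["v_mu"] > 0:  # anchor at the inoculum ratio
        times.append(0.0)
        lnr.append(math.log(traj0["v_mu"] / traj0["v_wt"]))
    for entry in outcome.dead_time_log:
        times.append(entry["time"])
        lnr.append(math.log(max(entry["v_mu"], 1) / max(entry["v_wt"], 1)))
    if len(times) < 2:
        return FitnessEstimate(float("nan"), float("nan"), (float("nan"),) * 2, len(times))
    if len(times) == 2:
        slope = (lnr[1] - lnr[0]) / (times[1] - times[0])
        return FitnessEstimate(slope, float("nan"), (times[0], times[-1]), 2)
    res = stats.linregress(times, lnr)
    return FitnessEstimate(
        float(res.slope), float(res.stderr), (times[0], times[-1]), len(times)
    )


def estimate_front_velocity(
    trajectory: pd.DataFrame, discard_fraction: float = 1.0 / 3.0
) -> FrontVelocityEstimate:
    """Front velocity by OLS on the treadmill-corrected peak-virion position.

    The first ``discard_fraction`` of the run (establishment transient) is
    discarded.  A plaque whose front never leaves the inoculated deme is
    reported as velocity 0 with ``expanded=False``.
    """
    t = trajectory["time"].to_numpy()
    pos = trajectory["front_pos"].to_numpy(dtype=float)
    if pos.max() <= 0:
        return FrontVelocityEstimate(0.0, 0.0, (float(t[0]), float(t[-1])), False)
    t_cut = t[0] + discard_fraction * (t[-1] - t[0])
    sel = t >= t_cut
    res = stats.linregress(t[sel], pos[sel])
    return FrontVelocityEstimate(
        float(res.slope), float(res.stderr), (float(t_cut), float(t[-1])), True
    )


def estimate_fixation_probability(
    config: SimConfig,
    n_reps: int = 20,
    base_seed: int = 0,
    runner=run_serial_passage,
) -> FixationEstimate:
    """Fraction of replicate runs in which the mutant fixes.

    Runs ending undecided count as non-fixation.  The binomial 95% CI is
    Clopper–Pearson.  Per-replicate seeds are spawned deterministically
    from ``base_seed``.
    """
    wins = {"mutant": 0, "wildtype": 0, "none": 0}
    for i in range(n_reps):
        seed = int(np.random.SeedSequence([base_seed, i]).generate_state(1)[0] % 2**31)
        out = runner(config, seed)
        out = out[0] if isinstance(out, tuple) else out
        wins[out.winner] += 1
    ci = stats.binomtest(wins["mutant"], n_reps).proportion_ci(0.95)
    return FixationEstimate(
        probability=wins["mutant"] / n_reps,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        n_mutant=wins["mutant"],
        n_wildtype=wins["wildtype"],
        n_none=wins["none"],
    )


def dead_time_diagnostic(outcome: CompetitionOutcome) -> pd.DataFrame:
    """Per-passage dead times: the wait between a strain's last lysis event
    and the transfer step.  NaN (flagged undefined) for passages in which
    a strain produced no lysis event."""
    df = pd.DataFrame(
        outcome.dead_time_log,
        columns=["passage", "time", "dead_time_wt", "dead_time_mu"],
    )
    df["wt_defined"] = df["dead_time_wt"].notna()
    df["mu_defined"] = df["dead_time_mu"].notna()
    return df
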