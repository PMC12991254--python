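"""Discrete-time stochastic engine for phage–bacteria dynamics.

Bacteria are explicit agents (flat numpy arrays, one row per live cell)
with two internal clocks: a growth clock that advances while the cell is
healthy, and a lysis countdown started at infection.  Free virions are
per-deme, per-strain integer counters.  Each timestep Δt applies, in
order: adsorption, infection, growth, lysis, decay, diffusion — then a
treadmill shift (plaque mode) or a dilution transfer (serial passage).

Adsorption uses an exact "receptor slot" reformulation of the sequential
failure rule.  The stated rule — each adsorption event picks a random
cell and fails with probability n_adsorbed/Amax, successes raising later
failure odds within the same step — is distributionally identical to each
event picking one of the cell's Amax receptor slots uniformly and
succeeding iff the slot is still free.  That equivalence lets a step with
tens of thousands of events be resolved with one sort instead of an
event-by-event loop.

Units: minutes, ml, μm.  Diffusion rates are supplied in μm²/s (the
conventional unit) and converted to μm²/min internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .life_history import (
    BacteriumParams,
    PhageStrain,
    _sample_burst_unchecked,
    default_bacterium,
)

__all__ = ["SimConfig", "Simulation", "DEFAULT_SUBSTEP_ORDER"]

DEFAULT_SUBSTEP_ORDER = (
    "adsorption",
    "infection",
    "growth",
    "lysis",
    "decay",
    "diffusion",
)

HEALTHY, INFECTED_WT, INFECTED_MU = 0, 1, 2
_MIN_CYCLE = 1.0  # min; floor for drawn growth-cycle lengths


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one simulation.

    Defaults correspond to the well-mixed serial-passage setup
    (Vol 1e-5 ml, 10,000 initial cells, carrying capacity 100,000,
    100 virions per strain); use ``n_demes > 1`` with the plaque values
    (Vol 1e-7 ml per deme, 100 cells = capacity per deme) for the spatial
    lawn.  ``conservative`` disables virion decay and super-adsorption
    (Amax = 1), the mode used to isolate the population-resonance
    mechanism.
    """

    strains: tuple[PhageStrain, PhageStrain]
    bacterium: BacteriumParams = field(default_factory=default_bacterium)
    dt: float = 0.01
    t_max: float = 600.0
    volume: float = 1e-5
    b0: int = 10_000
    carrying_capacity: int = 100_000
    v0: tuple[int, int] = (100, 100)
    n_demes: int = 1
    deme_length: float = 10.0
    treadmill_threshold: int = 30
    conservative: bool = False
    transfer_enabled: bool = True
    transfer_threshold_frac: float = 0.01
    dilution: float = 1e-3
    transfer_interval: float | None = None  # minutes; None = lysis-triggered
    sample_interval: float = 1.0
    substep_order: tuple[str, ...] = DEFAULT_SUBSTEP_ORDER
    record_events: bool = False  # keep per-step substep tallies

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.b0 < 0 or self.carrying_capacity < 0 or min(self.v0) < 0:
            raise ValueError("counts must be >= 0")
        if set(self.substep_order) != set(DEFAULT_SUBSTEP_ORDER):
            raise ValueError("substep_order must be a permutation of the six substeps")


class Simulation:
    """Mutable simulation state plus the substep implementations.

    All randomness flows through a single ``numpy.random.Generator`` seeded
    at construction, and the substep draw order is fixed, so identical
    (config, seed) pairs give bit-identical trajectories.
    """

    def __init__(self, config: SimConfig, seed: int | np.random.Generator = 0):
        self.config = config
        strains = config.strains
        bact = config.bacterium
        if config.conservative:
            strains = tuple(replace(s, decay_rate=0.0) for s in strains)
            bact = replace(bact, max_adsorbed=1)
        self.strains = strains
        self.bacterium = bact
        self.rng = (
            seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        )

        self._alpha = np.array([s.adsorption_rate for s in strains])
        self._delta = np.array([s.decay_rate for s in strains])
        self._diff = np.array([s.diffusion_rate for s in strains]) * 60.0  # μm²/min

        nd = config.n_demes
        cap = max(16, 2 * config.b0 * nd)
        self._cap = cap
        self.deme = np.zeros(cap, dtype=np.int32)
        self.state = np.zeros(cap, dtype=np.int8)
        self.g_elapsed = np.zeros(cap)
        self.g_cycle = np.zeros(cap)
        self.l_elapsed = np.zeros(cap)
        self.l_time = np.zeros(cap)
        self.ads = np.zeros((cap, 2), dtype=np.int32)
        self.ads_tot = np.zeros(cap, dtype=np.int32)  # running row sums of ads
        self.n = 0

        self.V = np.zeros((nd, 2), dtype=np.int64)
        self.time = 0.0
        self.step_count = 0
        self.cum_released = np.zeros(2, dtype=np.int64)
        self.cumulative_shift = 0
        self.n_transfers = 0
        self.last_lysis_time = [math.nan, math.nan]
        self.dead_time_log: list[dict] = []
        self.event_log: list[dict] = []
        self.tallies: dict = {}
        self._traj_rows: list[tuple] = []
        self._sample_every = max(1, round(config.sample_interval / config.dt))
        self._initialize()

    # ------------------------------------------------------------------
    # setup and array plumbing

    def _initialize(self):
        cfg = self.config
        for d in range(cfg.n_demes):
            self._add_fresh_cells(cfg.b0, d)
        # virions start in the (single) deme, or the leftmost deme of the lawn
        self.V[0, 0] = cfg.v0[0]
        self.V[0, 1] = cfg.v0[1]
        self._record()

    def _ensure_capacity(self, extra: int):
        need = self.n + extra
        if need <= self._cap:
            return
        new_cap = max(need, 2 * self._cap)
        for name in (
            "deme", "state", "g_elapsed", "g_cycle", "l_elapsed", "l_time", "ads_tot",
        ):
            arr = getattr(self, name)
            grown = np.zeros(new_cap, dtype=arr.dtype)
            grown[: self.n] = arr[: self.n]
            setattr(self, name, grown)
        grown = np.zeros((new_cap, 2), dtype=self.ads.dtype)
        grown[: self.n] = self.ads[: self.n]
        self.ads = grown
        self._cap = new_cap

    def _add_fresh_cells(self, count: int, deme: int):
        """Append healthy cells at random points of their growth cycle."""
        if count <= 0:
            return
        self._ensure_capacity(count)
        sl = slice(self.n, self.n + count)
        b = self.bacterium
        cycles = np.maximum(
            self.rng.normal(b.doubling_mean, b.doubling_std, count), _MIN_CYCLE
        )
        self.deme[sl] = deme
        self.state[sl] = HEALTHY
        self.g_cycle[sl] = cycles
        self.g_elapsed[sl] = self.rng.uniform(0.0, cycles)
        self.l_elapsed[sl] = 0.0
        self.l_time[sl] = 0.0
        self.ads[sl] = 0
        self.ads_tot[sl] = 0
        self.n += count

    def _delete_rows(self, idx: np.ndarray):
        """Swap-delete rows ``idx`` (sorted ascending, unique): surviving
        tail rows are moved into the freed slots."""
        k = len(idx)
        if k == 0:
            return
        n = self.n
        in_tail = idx >= n - k
        holes = idx[~in_tail]
        tail_alive = np.ones(k, dtype=bool)
        tail_alive[idx[in_tail] - (n - k)] = False
        keep_tail = (n - k) + np.nonzero(tail_alive)[0]
        for name in (
            "deme", "state", "g_elapsed", "g_cycle", "l_elapsed", "l_time", "ads_tot",
        ):
            arr = getattr(self, name)
            arr[holes] = arr[keep_tail]
        self.ads[holes] = self.ads[keep_tail]
        self.n = n - k

    # ------------------------------------------------------------------
    # convenience views / counts

    def deme_cell_counts(self) -> np.ndarray:
        return np.bincount(self.deme[: self.n], minlength=self.config.n_demes)

    def state_counts(self) -> tuple[int, int, int]:
        c = np.bincount(self.state[: self.n], minlength=3)
        return int(c[0]), int(c[1]), int(c[2])

    def infected_counts(self) -> np.ndarray:
        c = np.bincount(self.state[: self.n], minlength=3)
        return c[1:]

    def total_virions(self) -> np.ndarray:
        return self.V.sum(axis=0)

    def front_deme(self) -> int:
        return int(np.argmax(self.V.sum(axis=1)))

    def front_position(self) -> float:
        """Absolute front position [μm], treadmill-corrected."""
        return (self.front_deme() + self.cumulative_shift) * self.config.deme_length

    # ------------------------------------------------------------------
    # substeps

    def step_adsorption(self):
        """Poisson adsorption events, resolved with the receptor-slot rule.

        Event count per (deme, strain) ~ Poisson(α(B+I)V Δt / Vol), capped
        at the available free virions.  Every event targets a random cell
        (healthy or infected); success, with probability
        1 − n_adsorbed/Amax evaluated sequentially, consumes the virion and
        increments the target's adsorbed counter.  Failed events leave the
        virion free.
        """
        cfg = self.config
        counts = self.deme_cell_counts()
        lam = counts[:, None] * self.V * (cfg.dt / cfg.volume) * self._alpha[None, :]
        events = np.minimum(self.rng.poisson(lam), self.V)
        total = int(events.sum())
        self.tallies["adsorbed"] = np.zeros(2, dtype=np.int64)
        self.tallies["super_adsorbed"] = np.zeros(2, dtype=np.int64)
        if total == 0:
            return
        amax = self.bacterium.max_adsorbed
        flat = events.ravel()
        src = np.repeat(np.arange(flat.size), flat)
        d_e = (src // 2).astype(np.int64)
        s_e = (src % 2).astype(np.int64)

        if cfg.n_demes == 1:
            tgt = np.floor(self.rng.random(total) * self.n).astype(np.int64)
        else:
            # group only the cells of demes that actually have events
            active = events.sum(axis=1) > 0
            sel = np.nonzero(active[self.deme[: self.n]])[0]
            d_sub = self.deme[sel]
            order = np.argsort(d_sub, kind="stable")
            sub_counts = np.bincount(d_sub, minlength=cfg.n_demes)
            offs = np.concatenate(([0], np.cumsum(sub_counts)))
            pos = offs[d_e] + np.floor(
                self.rng.random(total) * sub_counts[d_e]
            ).astype(np.int64)
            tgt = sel[order[pos]]

        slot = self.rng.integers(0, amax, size=total)
        # random within-step ordering, then first-come-first-served per receptor
        perm = self.rng.permutation(total)
        tgt, slot, s_e, d_e = tgt[perm], slot[perm], s_e[perm], d_e[perm]
        key = tgt * amax + slot
        _, first = np.unique(key, return_index=True)
        # occupancy at step start = running adsorbed totals
        ok = first[slot[first] >= self.ads_tot[tgt[first]]]
        if len(ok) == 0:
            return
        t_ok, s_ok, d_ok = tgt[ok], s_e[ok], d_e[ok]
        np.add.at(self.ads, (t_ok, s_ok), 1)
        np.add.at(self.ads_tot, t_ok, 1)
        np.add.at(self.V, (d_ok, s_ok), -1)
        self.tallies["adsorbed"] = np.bincount(s_ok, minlength=2).astype(np.int64)
        sup = self.state[t_ok] != HEALTHY
        self.tallies["super_adsorbed"] = np.bincount(
            s_ok[sup], minlength=2
        ).astype(np.int64)

    def step_infection(self):
        """Healthy cells with adsorbed phage become infected.

        The infecting strain is a single Bernoulli draw on the proportion
        of adsorbed virions of each type; the realized lysis time is drawn
        from that strain's distribution, and the growth clock freezes.
        Already-infected cells never change fate (super-adsorption).
        """
        n = self.n
        ads = self.ads[:n]
        mask = (self.state[:n] == HEALTHY) & (self.ads_tot[:n] > 0)
        idx = np.nonzero(mask)[0]
        self.tallies["infections"] = np.zeros(2, dtype=np.int64)
        if len(idx) == 0:
            return
        tot = ads[idx].sum(axis=1)
        p_mu = ads[idx, 1] / tot
        is_mu = self.rng.random(len(idx)) < p_mu
        for s, sel in ((0, idx[~is_mu]), (1, idx[is_mu])):
            if len(sel) == 0:
                continue
            self.state[sel] = INFECTED_WT + s
            self.l_time[sel] = self.strains[s].lysis_dist.sample(len(sel), self.rng)
            self.l_elapsed[sel] = 0.0
            self.tallies["infections"][s] = len(sel)

    def step_growth(self):
        """Advance growth clocks; completed healthy cells divide up to C.

        At carrying capacity the completed clock is held (division
        deferred and retried), never aborted.  Mother and daughter both
        draw fresh cycle lengths.
        """
        cfg = self.config
        n = self.n
        healthy = self.state[:n] == HEALTHY
        self.g_elapsed[:n][healthy] += cfg.dt
        done = np.nonzero(healthy & (self.g_elapsed[:n] >= self.g_cycle[:n]))[0]
        self.tallies["divisions"] = 0
        if len(done) == 0:
            return
        # hold every completed clock at completion; dividers reset below
        self.g_elapsed[done] = self.g_cycle[done]
        counts = self.deme_cell_counts()
        allowed = np.maximum(cfg.carrying_capacity - counts, 0)
        if cfg.n_demes == 1:
            quota = int(allowed[0])
            if quota == 0:
                return
            if quota < len(done):
                pick = self.rng.choice(len(done), size=quota, replace=False)
                dividers = done[pick]
            else:
                dividers = done
        else:
            # only completed cells in demes with spare capacity can divide
            done = done[allowed[self.deme[done]] > 0]
            if len(done) == 0:
                return
            done = self.rng.permutation(done)
            d = self.deme[done]
            order = np.argsort(d, kind="stable")
            done_sorted = done[order]
            d_sorted = d[order]
            grp = np.bincount(d_sorted, minlength=cfg.n_demes)
            offs = np.concatenate(([0], np.cumsum(grp)))
            rank = np.arange(len(done_sorted)) - offs[d_sorted]
            dividers = done_sorted[rank < allowed[d_sorted]]
        k = len(dividers)
        if k == 0:
            return
        b = self.bacterium
        self.g_cycle[dividers] = np.maximum(
            self.rng.normal(b.doubling_mean, b.doubling_std, k), _MIN_CYCLE
        )
        self.g_elapsed[dividers] = 0.0
        self._ensure_capacity(k)
        sl = slice(self.n, self.n + k)
        self.deme[sl] = self.deme[dividers]
        self.state[sl] = HEALTHY
        self.g_cycle[sl] = np.maximum(
            self.rng.normal(b.doubling_mean, b.doubling_std, k), _MIN_CYCLE
        )
        self.g_elapsed[sl] = 0.0
        self.l_elapsed[sl] = 0.0
        self.l_time[sl] = 0.0
        self.ads[sl] = 0
        self.ads_tot[sl] = 0
        self.n += k
        self.tallies["divisions"] = k

    def step_lysis(self):
        """Advance lysis clocks; due cells burst and are removed.

        The burst is sampled from the infecting strain's model at the
        cell's realized lysis time; adsorbed virions of either strain on
        the lysing cell are lost.
        """
        n = self.n
        infected = self.state[:n] > HEALTHY
        self.l_elapsed[:n][infected] += self.config.dt
        due = np.nonzero(infected & (self.l_elapsed[:n] >= self.l_time[:n]))[0]
        self.tallies["released"] = np.zeros(2, dtype=np.int64)
        self.tallies["lysed"] = np.zeros(2, dtype=np.int64)
        if len(due) == 0:
            return
        for s in (0, 1):
            sel = due[self.state[due] == INFECTED_WT + s]
            if len(sel) == 0:
                continue
            bursts = _sample_burst_unchecked(
                self.strains[s].burst_model, self.l_time[sel], self.rng
            )
            np.add.at(self.V[:, s], self.deme[sel], bursts)
            self.tallies["released"][s] = int(bursts.sum())
            self.cum_released[s] += int(bursts.sum())
            self.tallies["lysed"][s] = len(sel)
            self.last_lysis_time[s] = self.time + self.config.dt
        self._delete_rows(due)

    def step_decay(self):
        """Free virions denature: per-strain Poisson(δ V Δt) losses."""
        lam = self.V * (self._delta[None, :] * self.config.dt)
        loss = np.minimum(self.rng.poisson(lam), self.V)
        self.V -= loss
        self.tallies["decayed"] = loss.sum(axis=0)

    def step_diffusion(self):
        """Virions hop between adjacent demes (reflecting boundaries).

        Per deme, strain and neighbour direction the migrant count is
        Poisson(D V Δt / (2Δx²)); totals are clamped (proportionally) at
        the available virions, so the lattice total is exactly conserved.
        """
        cfg = self.config
        if cfg.n_demes < 2:
            self.tallies["migrated"] = np.zeros(2, dtype=np.int64)
            return
        lam = self.V * (self._diff[None, :] * cfg.dt / (2.0 * cfg.deme_length**2))
        left, right = self.rng.poisson(lam, size=(2, *lam.shape))
        left[0, :] = 0
        right[-1, :] = 0
        tot = left + right
        over = tot > self.V
        if np.any(over):
            scaled = np.floor(left[over] * self.V[over] / tot[over]).astype(np.int64)
            right[over] = self.V[over] - scaled
            left[over] = scaled
            tot = left + right
        self.V -= tot
        self.V[:-1] += left[1:]
        self.V[1:] += right[:-1]
        self.tallies["migrated"] = tot.sum(axis=0)

    _SUBSTEP_FUNCS = {
        "adsorption": step_adsorption,
        "infection": step_infection,
        "growth": step_growth,
        "lysis": step_lysis,
        "decay": step_decay,
        "diffusion": step_diffusion,
    }

    # ------------------------------------------------------------------
    # boundary events

    def apply_treadmill(self):
        """Slide the spatial window to follow the infection front.

        While the deme with the most free virions (both strains) sits more
        than ``treadmill_threshold`` demes from the left edge, drop the
        leftmost deme, shift everything left and append a fresh deme of
        healthy cells at carrying capacity.
        """
        cfg = self.config
        if cfg.n_demes < 2:
            return
        tot = self.V.sum(axis=1)
        while int(np.argmax(tot)) > cfg.treadmill_threshold:
            gone = np.nonzero(self.deme[: self.n] == 0)[0]
            self._delete_rows(gone)
            self.deme[: self.n] -= 1
            self.V[:-1] = self.V[1:]
            self.V[-1] = 0
            self._add_fresh_cells(cfg.carrying_capacity, cfg.n_demes - 1)
            self.cumulative_shift += 1
            tot = self.V.sum(axis=1)

    def _transfer_due(self) -> bool:
        cfg = self.config
        if not cfg.transfer_enabled or cfg.n_demes != 1:
            return False
        if cfg.transfer_interval is not None:
            k = round(cfg.transfer_interval / cfg.dt)
            return k > 0 and self.step_count > 0 and self.step_count % k == 0
        return self.n < cfg.transfer_threshold_frac * cfg.b0

    def apply_transfer(self):
        """1000× dilution into fresh hosts.

        Every bacterium (with its clocks and infection state) and every
        free virion independently survives with probability ``dilution``;
        ``b0`` fresh healthy cells are then added.  The per-strain dead
        time (time since that strain's last lysis event this passage) is
        logged before diluting.
        """
        cfg = self.config
        now = self.time + self.config.dt  # end-of-step time, matching lysis stamps
        self.dead_time_log.append(
            {
                "passage": self.n_transfers,
                "time": now,
                "dead_time_wt": now - self.last_lysis_time[0],
                "dead_time_mu": now - self.last_lysis_time[1],
                "v_wt": int(self.V[:, 0].sum()),
                "v_mu": int(self.V[:, 1].sum()),
            }
        )
        self.predilution_V = self.V.copy()
        keep = np.nonzero(self.rng.random(self.n) < cfg.dilution)[0]
        k = len(keep)
        for name in (
            "deme", "state", "g_elapsed", "g_cycle", "l_elapsed", "l_time", "ads_tot",
        ):
            arr = getattr(self, name)
            arr[:k] = arr[keep]
        self.ads[:k] = self.ads[keep]
        self.n = k
        self.V = self.rng.binomial(self.V, cfg.dilution)
        self._add_fresh_cells(cfg.b0, 0)
        self.n_transfers += 1
        self.last_lysis_time = [math.nan, math.nan]

    # ------------------------------------------------------------------
    # stepping and trajectories

    def advance_one_step(self):
        """One Δt: the six substeps in order, then treadmill/transfer."""
        self.tallies = {}
        v_before = int(self.V.sum())
        for name in self.config.substep_order:
            self._SUBSTEP_FUNCS[name](self)
        self.tallies["virion_delta"] = int(self.V.sum()) - v_before
        self.apply_treadmill()
        self.tallies["transferred"] = False
        if self._transfer_due():
            self.apply_transfer()
            self.tallies["transferred"] = True
        self.step_count += 1
        self.time = self.step_count * self.config.dt
        if self.config.record_events:
            entry = {"time": self.time}
            for key, val in self.tallies.items():
                entry[key] = val.tolist() if isinstance(val, np.ndarray) else val
            self.event_log.append(entry)
        if self.step_count % self._sample_every == 0:
            self._record()

    def _record(self):
        h, iw, im = self.state_counts()
        self._traj_rows.append(
            (
                self.time,
                h,
                iw,
                im,
                int(self.V[:, 0].sum()),
                int(self.V[:, 1].sum()),
                self.cumulative_shift,
                self.front_deme(),
                self.front_position(),
                self.n_transfers,
                int(self.cum_released[0]),
                int(self.cum_released[1]),
            )
        )

    def run(self, t_end: float | None = None, stop=None):
        """Advance until ``t_end`` (default config.t_max).

        ``stop``, if given, is called after every step with the simulation
        and may return a truthy value to terminate early (its value is
        returned).
        """
        t_end = self.config.t_max if t_end is None else t_end
        n_steps = round(t_end / self.config.dt)
        while self.step_count < n_steps:
            self.advance_one_step()
            if stop is not None:
                verdict = stop(self)
                if verdict:
                    if self.step_count % self._sample_every != 0:
                        self._record()
                    return verdict
        if self.step_count % self._sample_every != 0:
            self._record()
        return None

    @property
    def trajectory(self) -> pd.DataFrame:
        return pd.DataFrame(
            self._traj_rows,
            columns=[
                "time",
                "healthy",
                "infected_wt",
                "infected_mu",
                "v_wt",
                "v_mu",
                "cumulative_shift",
                "front_deme",
                "front_pos",
                "n_transfers",
                "cum_rel_wt",
                "cum_rel_mu",
            ],
        )

    def write_trajectory_tsv(self, path):
        self.trajectory.to_csv(path, sep="\t", index=False)

    def write_event_log_ndjson(self, path):
        """Per-step substep tallies as newline-delimited JSON (requires
        ``record_events=True``)."""
        import json

        with open(path, "w") as fh:
            for entry in self.event_log:
                fh.write(json.dumps(entry))
                fh.write("\n")
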