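"""Parameter sweeps over mutant lysis-time parameters: fitness landscapes.

A sweep runs the chosen competition protocol over a grid of mutant
lysis-time parameters (mean × mean against a matched wild type, or
mean × std against a fixed wild type), with replicate runs per grid cell
and deterministic per-cell seeding, and collects the theory prediction Δk
alongside the simulated fixation probability, selection rate ΔF and (for
plaques) front velocity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import __version__
from .engine import SimConfig
from .growth_theory import growth_rate_difference
from .protocols import (
    estimate_fitness_difference,
    estimate_fitness_from_transfers,
    run_plaque_expansion,
    run_serial_passage,
)

__all__ = [
    "SweepSpec",
    "LandscapeGrid",
    "run_sweep",
    "resonance_scan",
    "detect_resonance_edge",
    "ResonanceEdge",
    "export_landscape",
    "cell_seed",
]


@dataclass(frozen=True)
class SweepSpec:
    """Specification of one landscape sweep.

    ``kind`` is ``mean_vs_mean`` (wild type and mutant means both scanned,
    shared std) or ``mean_vs_std`` (mutant mean on the y axis and mutant
    std on the x axis, wild type fixed).  ``base_config`` supplies the
    protocol (single deme → serial passage, several demes → plaque) and
    everything not being scanned.
    """

    kind: str  # "mean_vs_mean" | "mean_vs_std"
    mean_axis: tuple[float, ...]
    second_axis: tuple[float, ...]  # wildtype means, or mutant stds
    base_config: SimConfig
    family: str = "gaussian"
    shared_std: float = 0.01  # lysis std for both strains (mean_vs_mean)
    replicates: int = 5
    base_seed: int = 0

    def __post_init__(self):
        if self.kind not in ("mean_vs_mean", "mean_vs_std"):
            raise ValueError(f"unknown sweep kind {self.kind!r}")
        for ax in (self.mean_axis, self.second_axis):
            if len(ax) == 0 or np.any(np.diff(ax) <= 0):
                raise ValueError("axes must be non-empty and strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class LandscapeGrid:
    spec: SweepSpec
    delta_k: np.ndarray  # theory, shape (len(mean_axis), len(second_axis))
    fixation_prob: np.ndarray
    mean_delta_f: np.ndarray
    se_delta_f: np.ndarray
    mean_velocity: np.ndarray | None = None
    n_runs: np.ndarray | None = None


@dataclass(frozen=True)
class ResonanceEdge:
    dip_tau: float
    edge_tau: float
    dip_depth: float


def cell_seed(base_seed: int, cell_index: int, rep: int) -> int:
    """Deterministic per-run seed (< 2^31) for a sweep cell replicate."""
    return int(
        np.random.SeedSequence([base_seed, cell_index, rep]).generate_state(1)[0]
        % 2**31
    )


def _cell_strains(spec: SweepSpec, mean_mu: float, second: float):
    wt, mu = spec.base_config.strains
    if spec.kind == "mean_vs_mean":
        wt = wt.with_lysis(second, spec.shared_std, spec.family)
        mu = mu.with_lysis(mean_mu, spec.shared_std, spec.family)
    else:
        mu = mu.with_lysis(mean_mu, second, spec.family)
    return wt, mu


def run_sweep(spec: SweepSpec, progress: bool = False) -> LandscapeGrid:
    """Fill the landscape grid cell by cell.

    Individual failed runs are recorded as missing (NaN) rather than
    aborting the sweep.
    """
    ny, nx = len(spec.mean_axis), len(spec.second_axis)
    is_plaque = spec.base_config.n_demes > 1
    delta_k = np.full((ny, nx), np.nan)
    fix = np.full((ny, nx), np.nan)
    mdf = np.full((ny, nx), np.nan)
    sdf = np.full((ny, nx), np.nan)
    vel = np.full((ny, nx), np.nan) if is_plaque else None
    nrun = np.zeros((ny, nx), dtype=int)

    for i, mean_mu in enumerate(spec.mean_axis):
        for j, second in enumerate(spec.second_axis):
            wt, mu = _cell_strains(spec, mean_mu, second)
            delta_k[i, j] = growth_rate_difference(mu, wt)
            cfg = replace(spec.base_config, strains=(wt, mu))
            cell = i * nx + j
            dfs, vels, wins = [], [], 0
            for r in range(spec.replicates):
                seed = cell_seed(spec.base_seed, cell, r)
                try:
                    if is_plaque:
                        out, v = run_plaque_expansion(cfg, seed)
                        vels.append(v.velocity)
                    else:
                        out = run_serial_passage(cfg, seed)
                except Exception:  # failed run -> missing cell data
                    continue
                est = estimate_fitness_difference(out.trajectory)
                if est.defined:
                    dfs.append(est.delta_f)
                wins += out.winner == "mutant"
                nrun[i, j] += 1
            if nrun[i, j]:
                fix[i, j] = wins / nrun[i, j]
            if dfs:
                mdf[i, j] = float(np.mean(dfs))
                sdf[i, j] = float(np.std(dfs, ddof=1) / np.sqrt(len(dfs))) if len(dfs) > 1 else np.nan
            if is_plaque and vels:
                vel[i, j] = float(np.mean(vels))
            if progress:
                print(
                    f"cell ({i},{j}) mean_mu={mean_mu} second={second} "
                    f"fix={fix[i, j]:.2f} dF={mdf[i, j]:.4f}",
                    flush=True,
                )
    return LandscapeGrid(spec, delta_k, fix, mdf, sdf, vel, nrun)


def resonance_scan(
    base_config: SimConfig,
    tau_wt: float,
    tau_mu_grid,
    std: float = 0.01,
    replicates: int = 3,
    base_seed: int = 0,
    family: str = "gaussian",
    stop_at_fixation: bool = False,
) -> pd.DataFrame:
    """ΔF along a 1-D scan of the mutant mean lysis time.

    The wild type is fixed at ``tau_wt`` with the same (small) lysis std;
    this is the scan on which the population-resonance dip appears.  ΔF is
    estimated from the pre-dilution pools at passage boundaries, which
    stays defined when tightly synchronized lysis empties the free pools
    between bursts.
    """
    rows = []
    for idx, tau_mu in enumerate(tau_mu_grid):
        wt = base_config.strains[0].with_lysis(tau_wt, std, family)
        mu = base_config.strains[1].with_lysis(float(tau_mu), std, family)
        cfg = replace(base_config, strains=(wt, mu))
        dfs, wins, n = [], 0, 0
        for r in range(replicates):
            out = run_serial_passage(
                cfg, cell_seed(base_seed, idx, r), stop_at_fixation=stop_at_fixation
            )
            est = estimate_fitness_from_transfers(out)
            if est.defined:
                dfs.append(est.delta_f)
            wins += out.winner == "mutant"
            n += 1
        rows.append(
            {
                "tau_mu": float(tau_mu),
                "delta_f": float(np.mean(dfs)) if dfs else np.nan,
                "fixation": wins / n,
                "n_runs": n,
            }
        )
    return pd.DataFrame(rows)


def _smooth3(y: np.ndarray) -> np.ndarray:
    if len(y) < 3:
        return y.copy()
    s = y.copy()
    s[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
    return s


def detect_resonance_edge(tau_grid, delta_f, min_depth: float = 0.02) -> ResonanceEdge | None:
    """Locate the resonance dip and its lower edge on a ΔF scan.

    The dip is the deepest interior local minimum of the 3-point-smoothed
    scan, provided it falls at least ``min_depth`` [1/min] below the
    higher of the surrounding levels (shallower wiggles are replicate
    noise); the lower edge is the grid point just below the steepest fall
    into the dip — the point where a marginally shorter mutant lysis time
    stops incurring the dead-time penalty.  Returns None when no
    qualifying interior local minimum exists (flat or monotone scans).
    """
    tau = np.asarray(tau_grid, dtype=float)
    y = np.asarray(delta_f, dtype=float)
    if len(tau) < 3 or np.any(np.isnan(y)):
        return None
    s = _smooth3(y)
    interior = np.arange(1, len(s) - 1)
    is_min = (s[interior] < s[interior - 1]) & (s[interior] <= s[interior + 1])
    cands = interior[is_min]
    if len(cands) == 0:
        return None
    j = int(cands[np.argmin(s[cands])])
    depth = float(max(s[: j + 1].max(), s[j:].max()) - s[j])
    if depth < min_depth:
        return None
    # steepest raw fall below the dip
    drops = np.diff(y[: j + 1])
    if len(drops) == 0:
        return None
    i_star = int(np.argmin(drops))
    return ResonanceEdge(dip_tau=float(tau[j]), edge_tau=float(tau[i_star]), dip_depth=depth)


def export_landscape(grid: LandscapeGrid, out_dir) -> list[str]:
    """Write one CSV per measure plus a JSON manifest; byte-stable."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = grid.spec
    written = []
    measures = {
        "delta_k": grid.delta_k,
        "fixation_prob": grid.fixation_prob,
        "mean_delta_f": grid.mean_delta_f,
        "se_delta_f": grid.se_delta_f,
    }
    if grid.mean_velocity is not None:
        measures["mean_velocity"] = grid.mean_velocity
    for name, mat in measures.items():
        df = pd.DataFrame(
            mat,
            index=pd.Index(spec.mean_axis, name="mutant_mean_lysis"),
            columns=[f"{v:g}" for v in spec.second_axis],
        )
        path = out / f"{name}.csv"
        df.to_csv(path, float_format="%.10g")
        written.append(str(path))
    manifest = {
        "kind": spec.kind,
        "mean_axis": list(spec.mean_axis),
        "second_axis": list(spec.second_axis),
        "family": spec.family,
        "shared_std": spec.shared_std,
        "replicates": spec.replicates,
        "base_seed": spec.base_seed,
        "protocol": "plaque" if spec.base_config.n_demes > 1 else "serial_passage",
        "version": __version__,
        "measures": sorted(measures),
    }
    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(str(mpath))
    return written
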