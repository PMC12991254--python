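"""Configuration factories and YAML config-file loading.

The YAML schema mirrors the standard life-history symbols spelled out::

    wildtype:
      adsorption_rate: 3.0e-9      # ml/min
      decay_rate: 0.01             # 1/min
      diffusion_rate: 4.0          # μm²/s
      burst_model:
        kind: linear_with_eclipse  # normal | linear | linear_with_eclipse
        maturation_rate: 20.0      # virions/min (eclipse model)
        eclipse: 9.5               # min
        # effective_maturation_rate: 8.82   (linear model)
        # burst_mean: 150.0, burst_std: 50.0 (normal model)
      lysis:
        family: gaussian
        lysis_mean: 17.0
        lysis_std: 2.5
    mutant: { ... }                # omitted keys default to the wildtype's
    bacteria:
      doubling_mean: 20.0
      doubling_std: 2.0
      max_adsorbed: 100
    simulation:
      protocol: serial_passage     # or plaque
      dt: 0.01
      ...

Omitted sections fall back to the defaults, which reproduce the standard
serial-passage / plaque parameter sets.
"""

from __future__ import annotations

import yaml

from .engine import SimConfig
from .life_history import (
    BacteriumParams,
    BurstSizeModel,
    PhageStrain,
    default_strain,
    distribution_from_mean_std,
)

__all__ = [
    "serial_passage_config",
    "plaque_config",
    "scale_system",
    "load_config",
    "strain_from_dict",
]


def serial_passage_config(
    wildtype: PhageStrain | None = None,
    mutant: PhageStrain | None = None,
    bacterium: BacteriumParams | None = None,
    **overrides,
) -> SimConfig:
    """Well-mixed serial-passage defaults: Vol 1e-5 ml, B0 10,000,
    C 100,000, V0 100 per strain, dt 0.01 min, t_max 600 min."""
    wt = wildtype or default_strain("wildtype")
    mu = mutant or default_strain("mutant")
    kwargs = dict(
        strains=(wt, mu),
        bacterium=bacterium or BacteriumParams(),
        dt=0.01,
        t_max=600.0,
        volume=1e-5,
        b0=10_000,
        carrying_capacity=100_000,
        v0=(100, 100),
        n_demes=1,
        transfer_enabled=True,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def plaque_config(
    wildtype: PhageStrain | None = None,
    mutant: PhageStrain | None = None,
    bacterium: BacteriumParams | None = None,
    **overrides,
) -> SimConfig:
    """Plaque-expansion defaults: 60 demes of 10 μm / 1e-7 ml, 100 cells =
    carrying capacity per deme, 100 virions per strain inoculated in the
    leftmost deme, t_max 180 min, treadmill threshold 30 demes."""
    wt = wildtype or default_strain("wildtype")
    mu = mutant or default_strain("mutant")
    kwargs = dict(
        strains=(wt, mu),
        bacterium=bacterium or BacteriumParams(),
        dt=0.01,
        t_max=180.0,
        volume=1e-7,
        b0=100,
        carrying_capacity=100,
        v0=(100, 100),
        n_demes=60,
        deme_length=10.0,
        treadmill_threshold=30,
        transfer_enabled=False,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def scale_system(config: SimConfig, factor: float) -> SimConfig:
    """Rescale the absolute system size (volume and all counts) by
    ``factor``, leaving concentrations and per-capita dynamics unchanged.

    The dynamics are scale invariant, so a 0.1× system is a faithful,
    cheaper stand-in for the full-size protocol up to sampling noise.
    """
    from dataclasses import replace

    return replace(
        config,
        volume=config.volume * factor,
        b0=int(round(config.b0 * factor)),
        carrying_capacity=int(round(config.carrying_capacity * factor)),
        v0=tuple(int(round(v * factor)) for v in config.v0),
    )


# ---------------------------------------------------------------------------
# YAML


def _burst_from_dict(d: dict) -> BurstSizeModel:
    kind = d.get("kind", "linear_with_eclipse")
    if kind == "normal":
        return BurstSizeModel(
            "normal",
            {"burst_mean": float(d["burst_mean"]), "burst_std": float(d["burst_std"])},
        )
    if kind == "linear":
        return BurstSizeModel("linear", {"rate": float(d["effective_maturation_rate"])})
    return BurstSizeModel(
        "linear_with_eclipse",
        {"rate": float(d["maturation_rate"]), "eclipse": float(d["eclipse"])},
    )


def strain_from_dict(d: dict, label: str, base: PhageStrain | None = None) -> PhageStrain:
    base = base or default_strain(label)
    lys = d.get("lysis", {})
    lysis = (
        distribution_from_mean_std(
            lys.get("family", "gaussian"),
            float(lys["lysis_mean"]),
            float(lys.get("lysis_std", 0.0)),
        )
        if "lysis_mean" in lys
        else base.lysis_dist
    )
    return PhageStrain(
        label=label,
        adsorption_rate=float(d.get("adsorption_rate", base.adsorption_rate)),
        decay_rate=float(d.get("decay_rate", base.decay_rate)),
        diffusion_rate=float(d.get("diffusion_rate", base.diffusion_rate)),
        burst_model=_burst_from_dict(d["burst_model"]) if "burst_model" in d else base.burst_model,
        lysis_dist=lysis,
    )


def load_config(path) -> SimConfig:
    """Build a :class:`SimConfig` from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    wt = strain_from_dict(doc.get("wildtype", {}), "wildtype")
    mu = strain_from_dict(doc.get("mutant", {}), "mutant", base=wt)
    bact_d = doc.get("bacteria", {})
    bact = BacteriumParams(
        doubling_mean=float(bact_d.get("doubling_mean", 20.0)),
        doubling_std=float(bact_d.get("doubling_std", 2.0)),
        max_adsorbed=int(bact_d.get("max_adsorbed", 100)),
    )
    sim = dict(doc.get("simulation", {}))
    protocol = sim.pop("protocol", "serial_passage")
    factory = plaque_config if protocol == "plaque" else serial_passage_config
    if "v0" in sim:
        sim["v0"] = tuple(int(v) for v in sim["v0"])
    return factory(wildtype=wt, mutant=mu, bacterium=bact, **sim)
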