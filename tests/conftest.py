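import numpy as np
import pytest

import phagesim as ps


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scaled_serial_base():
    """0.1x-size serial-passage base config (eclipse model strains).

    The model is scale invariant, so the reduced system is a faithful,
    cheaper stand-in for the full-size protocol; the invariance itself is
    checked by a dedicated test.
    """
    wt = ps.default_strain("wildtype", "linear_with_eclipse")
    mu = ps.default_strain("mutant", "linear_with_eclipse")
    return ps.scale_system(ps.serial_passage_config(wt, mu, t_max=300.0), 0.1)


RESONANCE_TAUS = np.arange(10.0, 16.5, 1.0)
RESONANCE_TAU_WT = 24.0


@pytest.fixture(scope="session")
def resonance_scan_default(scaled_serial_base):
    """ΔF/fixation scan across the resonance stripe, default conditions."""
    return ps.resonance_scan(
        scaled_serial_base,
        tau_wt=RESONANCE_TAU_WT,
        tau_mu_grid=RESONANCE_TAUS,
        std=0.01,
        replicates=3,
        base_seed=7,
    )


@pytest.fixture(scope="session")
def resonance_scan_conservative(scaled_serial_base):
    """Same scan with decay and super-adsorption disabled."""
    from dataclasses import replace

    return ps.resonance_scan(
        replace(scaled_serial_base, conservative=True),
        tau_wt=RESONANCE_TAU_WT,
        tau_mu_grid=RESONANCE_TAUS,
        std=0.01,
        replicates=3,
        base_seed=7,
    )
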