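"""Effective growth rate of a phage in isolation under the three
lysis-time/burst-size trade-off models.

Computes k = ∫ p(τ) ln β(τ)/τ dτ for a Gaussian lysis-time distribution,
shows how noise shifts it in opposite directions depending on the
trade-off, and locates the optimal mean lysis time of the eclipse model.
"""

import phagesim as ps
from phagesim.life_history import _DEFAULT_BURST

for name, model in _DEFAULT_BURST.items():
    k_det = ps.effective_growth_rate(
        ps.LysisTimeDistribution("delta", {"tau": 17.0}), model
    ).k
    k_noisy = ps.effective_growth_rate(
        ps.distribution_from_mean_std("gaussian", 17.0, 2.5), model
    ).k
    print(f"{name:20s}  k(std=0) = {k_det:.5f}/min   k(std=2.5) = {k_noisy:.5f}/min")

print()
print("All three models are calibrated so a 17-min lysis yields 150 virions,")
print("hence identical deterministic rates; noise raises k for the normal and")
print("linear models (convexity of ln beta/tau) and lowers it for the eclipse")
print("model, whose short cycles are unproductive.")
print()

ecl = _DEFAULT_BURST["linear_with_eclipse"]
for std in (0.0, 2.0, 4.0):
    res = ps.optimal_mean_lysis_time(ecl, std=std)
    print(f"eclipse model, lysis std {std:3.1f} min: "
          f"optimal mean lysis {res.tau_opt:6.2f} min, k* = {res.k_opt:.5f}/min")
print()
print("The optimum shifts to longer lysis times and lower peak growth as the")
print("lysis-time distribution widens.")
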