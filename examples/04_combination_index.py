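"""Score drug-pair synergy with the Chou-Talalay combination index.

Fits the median-effect equation fa/(1-fa) = (D/Dm)^m to each single-agent
dose-response curve, then evaluates combinations: CI < 1 synergism, CI = 1
additive, CI > 1 antagonism.
"""

import nersig as ns

# Two simulated single-agent curves with mild measurement noise
curve_a = ns.simulate_dose_response(
    ns.MedianEffectSimConfig(seed=1, m_true=2.0, dm_true=5.0, fa_noise_sd=0.05, drug="drugA")
)
curve_b = ns.simulate_dose_response(
    ns.MedianEffectSimConfig(seed=2, m_true=1.0, dm_true=2.0,
                             doses=(0.25, 0.5, 1.0, 2.0, 4.0, 8.0),
                             fa_noise_sd=0.05, drug="drugB")
)
fit_a = ns.fit_median_effect(curve_a)
fit_b = ns.fit_median_effect(curve_b)
for fit in (fit_a, fit_b):
    print(f"{fit.drug}: m = {fit.m:.3f}, Dm = {fit.dm:.3f}, r = {fit.r:.4f}")
# m is the curve steepness, Dm the dose giving 50% effect, r the linear-fit
# correlation (r near 1 means the median-effect model describes the data).

fa = 0.6  # observed fraction affected for each combination below
dx_a, dx_b = ns.dose_for_effect(fit_a, fa), ns.dose_for_effect(fit_b, fa)
print(f"single-agent doses for fa={fa}: drugA {dx_a:.3f}, drugB {dx_b:.3f}")

for d1, d2, label in [
    (0.25 * dx_a, 0.25 * dx_b, "quarter doses reaching the same effect"),
    (0.50 * dx_a, 0.50 * dx_b, "half doses"),
    (1.00 * dx_a, 1.00 * dx_b, "full single-agent doses"),
]:
    res = ns.combination_index(fit_a, fit_b, d1, d2, fa)
    print(f"  d1={d1:.3f}, d2={d2:.3f}: CI = {res.ci:.3f} -> {res.call}  ({label})")
# A combination achieving fa=0.6 at quarter single-agent doses is strongly
# synergistic (CI = 0.5); matching full doses of both drugs is antagonistic
# (CI = 2): each drug alone would already have produced the effect.
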