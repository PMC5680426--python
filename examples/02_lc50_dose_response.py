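"""LC50 estimation from a simulated acute-exposure experiment.

Generates mortality under the study design (2 population types x 5 ponds x
5 chloride concentrations x 4 replicate units of 10 larvae), fits a
binomial logit dose-response GLM separately per population type, and
reports LC50 = -intercept/slope with a delta-method 95% interval.
"""

from evotox import estimate_lc50, fit_binomial_glm, nacl_to_chloride, simulate_mortality
from evotox.simulate import MortalitySimConfig

print("treatments 6.3, 8.4, 10.7, 12 g/L NaCl as chloride:",
      nacl_to_chloride([6.3, 8.4, 10.7, 12.0], round_to=100), "mg/L")
print()

cfg = MortalitySimConfig(seed=4)  # truths: roadside 3412, woodland 4395 mg/L
table = simulate_mortality(cfg)
print(f"simulated {len(table)} experimental units")

for ptype, truth in (("roadside", cfg.roadside_lc50), ("woodland", cfg.woodland_lc50)):
    sub = table[table["type"] == ptype].reset_index(drop=True)
    est = estimate_lc50(fit_binomial_glm(sub), population_label=ptype)
    print(
        f"{ptype:9s} LC50 = {est.lc50:7.0f} mg/L Cl "
        f"(95% CI {est.ci_low:.0f}-{est.ci_high:.0f}; simulated truth {truth:.0f})"
    )

print()
print("Roadside populations are simulated as more salt-sensitive (lower")
print("LC50), the pattern reported for wood frog populations with a history")
print("of road-salt exposure; each CI should usually bracket its truth.")
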